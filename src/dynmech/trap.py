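"""Optical-trap trace analysis: calibration, stall detection, statistics.

The analysis chain mirrors a fixed-trap stall-force assay:

1. raw 5 kHz traces are block-mean downsampled to the 250 Hz analysis
   rate;
2. trap stiffness is calibrated from the Lorentzian fit to the power
   spectrum of a trapped bead, ``S(f) = D / (pi^2 (fc^2 + f^2))`` with
   ``stiffness = 2 pi gamma fc``;
3. stalls are detected as stationary periods at force above a minimum
   (wild-type criteria: > 2.5 pN for > 100 ms, followed by a snap-back
   of the bead to the trap center; mutant criteria: > 1 pN for
   > 150 ms, snap-back optional).  "Stationary" means every sample's
   force lies within ``stationary_tolerance`` of the trace's running
   median over a 100 ms window;
4. the stall force is the mean force over the last 20% of the event,
   the stall time the total time the force spends at >= 80% of that
   stall force within the event;
5. population statistics: a pooled normalized force histogram fitted
   with 3 Gaussians (the near-0 pN component is the unbound dwell and
   can be subtracted), and a double-exponential fit to the stall-time
   survival curve (1-CDF).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit, least_squares
from scipy.signal import welch

from ._fitting import GaussianComponent, fit_gaussian_sum, gaussian_sum
from .trace import ForceTrace

__all__ = [
    "TrapCalibration",
    "StallCriteria",
    "StallEvent",
    "ForceSamplingFit",
    "StallTimeFit",
    "StallSummary",
    "CalibrationError",
    "downsample",
    "fit_lorentzian",
    "calibrate_stiffness",
    "detect_stalls",
    "stall_force",
    "stall_time",
    "force_sampling_fit",
    "stall_time_survival_fit",
    "summarize_stalls",
    "wild_type_criteria",
    "mutant_criteria",
    "write_events_csv",
]

ANALYSIS_RATE = 250.0  # Hz


class CalibrationError(RuntimeError):
    """Power-spectrum calibration failed; the message carries diagnostics."""


# ------------------------------------------------------------------ criteria


@dataclass
class StallCriteria:
    """Detection thresholds for stationary high-force events."""

    min_force: float  # pN
    min_duration: float  # s
    stationary_tolerance: float = 0.75  # pN, band around the running median
    stationary_window: float = 0.1  # s
    snap_back_required: bool = True
    snap_back_max_interval: float = 0.02  # s
    snap_back_min_drop: float = 2.0  # pN
    snap_back_floor: float = 0.5  # pN; a drop below this always qualifies

    def __post_init__(self) -> None:
        if self.min_force <= 0 or self.min_duration <= 0:
            raise ValueError("min_force and min_duration must be positive")


def wild_type_criteria(**overrides) -> StallCriteria:
    """Stationary > 2.5 pN for > 100 ms, snap-back required."""
    return StallCriteria(min_force=2.5, min_duration=0.1, **overrides)


def mutant_criteria(**overrides) -> StallCriteria:
    """Stationary > 1 pN for > 150 ms; snap-back not required, so both
    low-force pauses and stalls are admitted."""
    overrides.setdefault("snap_back_required", False)
    return StallCriteria(min_force=1.0, min_duration=0.15, **overrides)


# --------------------------------------------------------------- downsampling


def downsample(trace: ForceTrace, target_rate: float = ANALYSIS_RATE) -> ForceTrace:
    """Non-overlapping block-mean downsampling (noise reduction, not decimation)."""
    factor = trace.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {trace.sampling_rate} Hz is not an integer multiple "
            f"of target rate {target_rate} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return trace
    n_blocks = trace.n_samples // factor
    sl = slice(0, n_blocks * factor)

    def block_mean(x: np.ndarray) -> np.ndarray:
        return x[sl].reshape(n_blocks, factor).mean(axis=1)

    metadata = dict(trace.metadata)
    metadata["original_sampling_rate_hz"] = trace.sampling_rate
    return ForceTrace(
        time=block_mean(trace.time),
        position=block_mean(trace.position),
        force=block_mean(trace.force),
        sampling_rate=target_rate,
        trap_stiffness=trace.trap_stiffness,
        metadata=metadata,
    )


# ---------------------------------------------------------------- calibration


@dataclass
class TrapCalibration:
    corner_frequency: float  # Hz
    diffusion_plateau: float  # nm^2/Hz at f=0: D/(pi^2 fc^2)
    stiffness: float  # pN/nm
    fit_range: tuple[float, float]
    residual: float

    def __post_init__(self) -> None:
        if self.corner_frequency <= 0 or self.stiffness <= 0:
            raise ValueError("corner frequency and stiffness must be positive")


def _lorentzian(f: np.ndarray, fc: float, d: float, fs: float | None, n_alias: int) -> np.ndarray:
    s = d / (np.pi**2 * (fc**2 + f**2))
    if fs is not None:
        for k in range(1, n_alias + 1):
            s = s + d / (np.pi**2 * (fc**2 + (k * fs - f) ** 2))
            s = s + d / (np.pi**2 * (fc**2 + (k * fs + f) ** 2))
    return s


def fit_lorentzian(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit_range: tuple[float, float] | None = None,
    fs: float | None = None,
    n_alias: int = 0,
) -> tuple[float, float, float]:
    """Least-squares Lorentzian fit to a one-sided power spectrum.

    Returns (corner frequency Hz, diffusion constant nm^2/s, residual).
    Relative-error weighting is used (periodogram noise scales with the
    spectrum).  ``n_alias > 0`` adds folded Lorentzian terms at
    multiples of the sampling rate ``fs``, matching the spectrum of a
    discretely sampled bead.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    keep = psd > 0
    if fit_range is not None:
        keep &= (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f, s = freqs[keep], psd[keep]
    if f.size < 5:
        raise CalibrationError("too few spectral points in the fit range")
    # moment-based initialization: fc from the half-power point
    s0 = np.median(s[: max(3, f.size // 20)])
    below = np.flatnonzero(s < s0 / 2)
    fc0 = f[below[0]] if below.size else f[f.size // 2]
    d0 = s0 * np.pi**2 * fc0**2

    def resid(logp: np.ndarray) -> np.ndarray:
        fc, d = np.exp(logp)
        return _lorentzian(f, fc, d, fs, n_alias) / s - 1.0

    sol = least_squares(resid, np.log([max(fc0, 1e-3), max(d0, 1e-12)]))
    if not sol.success:
        raise CalibrationError(
            f"Lorentzian fit failed: {sol.message}; init fc={fc0:.3g}, D={d0:.3g}"
        )
    fc, d = np.exp(sol.x)
    residual = float(np.sqrt(np.mean(sol.fun**2)))
    return float(fc), float(d), residual


def calibrate_stiffness(
    trace: ForceTrace,
    temperature: float,
    drag_coefficient: float,
    fit_range: tuple[float, float] | None = None,
    nperseg: int = 8192,
) -> TrapCalibration:
    """Trap stiffness from the Lorentzian fit to the bead power spectrum.

    The spectrum is Welch-averaged; the fitted model includes ten
    spectral folds to account for the finite sampling rate, and
    ``stiffness = 2 pi gamma fc``.
    """
    del temperature  # stiffness needs only gamma and fc; kept for the record
    if trace.duration < 1.0:
        raise CalibrationError("need at least 1 s of data to calibrate")
    fs = trace.sampling_rate
    freqs, psd = welch(trace.position, fs=fs, nperseg=min(nperseg, trace.n_samples))
    if fit_range is None:
        fit_range = (max(5.0, freqs[1]), 0.45 * fs)
    fc, d, residual = fit_lorentzian(freqs, psd, fit_range, fs=fs, n_alias=10)
    stiffness = 2.0 * np.pi * drag_coefficient * fc
    return TrapCalibration(
        corner_frequency=fc,
        diffusion_plateau=d / (np.pi**2 * fc**2),
        stiffness=stiffness,
        fit_range=fit_range,
        residual=residual,
    )


# ------------------------------------------------------------ stall detection


@dataclass
class StallEvent:
    """One detected stall: interval, stall force, stall time, detachment flag."""

    start: float  # s
    end: float  # s
    stall_force: float  # pN
    stall_time: float  # s
    detached: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


def _indices(trace: ForceTrace, t: float) -> int:
    return int(round((t - trace.time[0]) * trace.sampling_rate))


def _running_median(force: np.ndarray, window_samples: int) -> np.ndarray:
    window_samples = max(1, window_samples)
    if window_samples % 2 == 0:
        window_samples += 1
    return median_filter(force, size=window_samples, mode="nearest")


def detect_stalls(trace: ForceTrace, criteria: StallCriteria) -> list[StallEvent]:
    """Maximal stationary high-force intervals satisfying the criteria.

    A sample is a candidate when its force is at least ``min_force``
    and deviates from the 100 ms running median by at most
    ``stationary_tolerance``.  Maximal candidate runs longer than
    ``min_duration`` become events; when ``snap_back_required`` the run
    must be followed, within ``snap_back_max_interval``, by a sample
    whose force has dropped by ``snap_back_min_drop`` below the event's
    median force or below ``snap_back_floor``.  Events are disjoint and
    time-ordered.
    """
    n = trace.n_samples
    if n == 0:
        return []
    force = trace.force
    fs = trace.sampling_rate
    window = int(round(criteria.stationary_window * fs))
    med = _running_median(force, window)
    candidate = (force >= criteria.min_force) & (
        np.abs(force - med) <= criteria.stationary_tolerance
    )
    events: list[StallEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], candidate.view(np.int8), [0]))))
    for i0, i1 in zip(edges[::2], edges[1::2] - 1):
        duration = (i1 - i0) / fs
        if duration <= criteria.min_duration:
            continue
        event_median = float(np.median(force[i0 : i1 + 1]))
        detached = _has_snap_back(force, fs, i1, event_median, criteria)
        if criteria.snap_back_required and not detached:
            continue
        event = StallEvent(
            start=float(trace.time[i0]),
            end=float(trace.time[i1]),
            stall_force=0.0,
            stall_time=0.0,
            detached=detached,
        )
        event.stall_force = stall_force(trace, event)
        event.stall_time = stall_time(trace, event)
        events.append(event)
    return events


def _has_snap_back(
    force: np.ndarray, fs: float, end_idx: int, event_median: float, criteria: StallCriteria
) -> bool:
    lo = end_idx + 1
    hi = min(force.size, end_idx + 1 + int(round(criteria.snap_back_max_interval * fs)))
    if lo >= hi:
        return False
    after = force[lo:hi]
    return bool(
        np.any(
            (after <= event_median - criteria.snap_back_min_drop)
            | (after < criteria.snap_back_floor)
        )
    )


def stall_force(trace: ForceTrace, event: StallEvent) -> float:
    """Mean force over the last 20% of the event (end sample inclusive)."""
    i0, i1 = _indices(trace, event.start), _indices(trace, event.end)
    w0 = int(np.ceil(i0 + 0.8 * (i1 - i0) - 1e-9))
    window = trace.force[w0 : i1 + 1]
    if window.size < 2:
        raise ValueError("fewer than 2 samples in the last-20% window")
    return float(np.mean(window))


def stall_time(trace: ForceTrace, event: StallEvent) -> float:
    """Total time within the event at force >= 80% of the stall force."""
    sf = event.stall_force if event.stall_force else stall_force(trace, event)
    i0, i1 = _indices(trace, event.start), _indices(trace, event.end)
    qualifying = trace.force[i0:i1] >= 0.8 * sf  # end sample excluded
    return float(np.count_nonzero(qualifying) / trace.sampling_rate)


# -------------------------------------------------------- population statistics


@dataclass
class ForceSamplingFit:
    """Gaussian-sum fit to the pooled normalized force histogram."""

    bin_edges: np.ndarray
    normalized_density: np.ndarray
    components: list[GaussianComponent]
    zero_peak_index: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def _zero_like(self) -> list[int]:
        """Components belonging to the unbound near-0 peak."""
        zero = self.components[self.zero_peak_index]
        bin_width = float(self.bin_edges[1] - self.bin_edges[0])
        halfwidth = max(2.0 * abs(zero.sd), bin_width)
        return [
            i for i, c in enumerate(self.components) if abs(c.mean) <= halfwidth
        ]

    def subtracted_density(self) -> np.ndarray:
        """Histogram with the unbound (near-0 pN) peak removed, renormalized."""
        x = self.bin_centers
        sub = self.normalized_density.copy()
        for i in self._zero_like():
            sub = sub - self.components[i].pdf(x)
        sub = np.clip(sub, 0.0, None)
        bin_width = float(self.bin_edges[1] - self.bin_edges[0])
        mass = sub.sum() * bin_width
        return sub / mass if mass > 0 else sub

    def residual_mass_after_subtraction(self) -> float:
        """Histogram mass not attributed to the near-0 unbound peak."""
        x = self.bin_centers
        sub = self.normalized_density.copy()
        for i in self._zero_like():
            sub = sub - self.components[i].pdf(x)
        bin_width = float(self.bin_edges[1] - self.bin_edges[0])
        return float(np.clip(sub, 0.0, None).sum() * bin_width)


def force_sampling_fit(
    traces: Iterable[ForceTrace] | Iterable[np.ndarray],
    n_components: int = 3,
    bin_width: float = 0.25,
) -> ForceSamplingFit:
    """Pooled force histogram fitted with ``n_components`` Gaussians.

    The component with mean nearest 0 pN is the unbound dwell
    (``zero_peak_index``); :meth:`ForceSamplingFit.subtracted_density`
    exposes the histogram with that peak removed.
    """
    samples = []
    for item in traces:
        samples.append(item.force if isinstance(item, ForceTrace) else np.asarray(item))
    if not samples:
        raise ValueError("need at least one trace")
    force = np.concatenate(samples)
    lo = np.floor(force.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(force.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(force, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    components = fit_gaussian_sum(centers, density, n_components)
    zero_idx = int(np.argmin([abs(c.mean) for c in components]))
    return ForceSamplingFit(
        bin_edges=edges,
        normalized_density=density,
        components=components,
        zero_peak_index=zero_idx,
    )


@dataclass
class StallTimeFit:
    """Double-exponential fit to the stall-time survival curve."""

    tau_fast: float
    tau_slow: float
    weight_fast: float
    standard_errors: tuple[float, float]  # SE of (tau_fast, tau_slow)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_fast > self.tau_slow + 1e-12:
            raise ValueError("tau_fast must not exceed tau_slow")


def _double_exp(t: np.ndarray, w: float, tau1: float, tau2: float) -> np.ndarray:
    return w * np.exp(-t / tau1) + (1.0 - w) * np.exp(-t / tau2)


def stall_time_survival_fit(stall_times: Sequence[float]) -> StallTimeFit:
    """Fit ``w exp(-t/tau1) + (1-w) exp(-t/tau2)`` to the empirical 1-CDF.

    Initialized from a two-piece log-linear fit of the survival curve.
    When the two time constants agree within 10% the data are
    effectively single-exponential: the fit is redone with one
    exponential and flagged ``degenerate``.
    """
    times = np.sort(np.asarray(stall_times, dtype=float))
    n = times.size
    if n < 20:
        raise ValueError("need at least 20 stall times")
    if np.ptp(times) <= 0:
        raise ValueError("degenerate data: all stall times are equal")
    survival = 1.0 - np.arange(n) / n  # S(t_i) = P(T >= t_i)

    # two-piece log-linear initialization
    head = slice(0, max(5, n // 3))
    tail = slice(max(0, n - max(5, n // 3)), n)
    tau1_0 = _loglinear_tau(times[head], survival[head])
    tau2_0 = _loglinear_tau(times[tail], survival[tail])
    tau1_0, tau2_0 = sorted((tau1_0, tau2_0))

    popt, pcov = curve_fit(
        _double_exp, times, survival,
        p0=[0.5, tau1_0, tau2_0],
        bounds=([0.0, 1e-6, 1e-6], [1.0, np.inf, np.inf]),
        maxfev=20000,
    )
    w, tau1, tau2 = popt
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        w = 1.0 - w
        popt = np.array([w, tau1, tau2])
    if abs(tau2 - tau1) / tau2 < 0.10:
        popt_s, pcov_s = curve_fit(
            lambda t, tau: np.exp(-t / tau), times, survival,
            p0=[0.5 * (tau1 + tau2)], maxfev=20000,
        )
        tau = float(popt_s[0])
        se = float(np.sqrt(pcov_s[0, 0]))
        return StallTimeFit(
            tau_fast=tau, tau_slow=tau, weight_fast=1.0,
            standard_errors=(se, se), degenerate=True,
        )
    se = np.sqrt(np.diag(pcov))
    return StallTimeFit(
        tau_fast=float(tau1),
        tau_slow=float(tau2),
        weight_fast=float(w),
        standard_errors=(float(se[1]), float(se[2])),
    )


def _loglinear_tau(t: np.ndarray, s: np.ndarray) -> float:
    keep = s > 0
    t, s = t[keep], s[keep]
    if t.size < 2 or np.ptp(t) <= 0:
        return 1.0
    slope = np.polyfit(t, np.log(s), 1)[0]
    return float(-1.0 / slope) if slope < 0 else 1.0


# ------------------------------------------------------------------- summaries


@dataclass
class StallSummary:
    """Mean stall force +/- SEM with the number of stalls
    (SEM uses the n-1 standard deviation)."""

    mean_stall_force: float
    sem: float  # nan when n == 1
    n: int


def summarize_stalls(events: Sequence[StallEvent]) -> StallSummary:
    if not events:
        raise ValueError("need at least one event")
    forces = np.array([e.stall_force for e in events])
    n = forces.size
    sem = float(forces.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return StallSummary(mean_stall_force=float(forces.mean()), sem=sem, n=n)


def write_events_csv(events: Sequence[StallEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
            "stall_force_pN": [e.stall_force for e in events],
            "stall_time_s": [e.stall_time for e in events],
            "detached": [e.detached for e in events],
        }
    ).to_csv(path, index=False)
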