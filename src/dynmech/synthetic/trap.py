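"""Brownian-dynamics simulation of a trapped bead driven by a motor.

Two generators live here.  :func:`simulate_ou_bead` produces a pure
Ornstein-Uhlenbeck (OU) bead in a harmonic trap — the calibration
standard, whose position variance obeys equipartition (kBT/kappa) and
whose power spectrum is Lorentzian with corner frequency
``fc = kappa / (2 pi gamma)``.

:func:`simulate_bead_trace` adds a motor that pulls the bead tether
along the microtubule against the trap.  The motor advances with the
load-reduced velocity ``v(F) = v0 * max(0, 1 - F/F_detach)**w``, stalls
when the tether load reaches a per-attachment detachment force sampled
from a Gaussian, dwells there for an exponential time, then detaches
with the bead snapping back to the trap center.  In "mutant mode"
(``pause_probability_per_s > 0``) the motor additionally pauses at low
forces inside ``pause_force_band``, mimicking the load-sensitive
pausing phenotype.  Every stall, pause and detachment is logged with
ground truth so downstream detectors can be scored.

The bead is integrated with the *exact* discrete OU update about the
moving tether point (no Euler step-size bias): with
``a = exp(-dt/tau)``, ``tau = gamma/kappa``,

    x[i+1] = m + (x[i] - m) * a + sqrt(kBT/kappa * (1 - a^2)) * xi.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from ..constants import BOLTZMANN_PN_NM
from ..trace import ForceTrace

__all__ = [
    "TrapSimParams",
    "MotorModelParams",
    "TrueEvent",
    "TrueEventLog",
    "simulate_ou_bead",
    "simulate_bead_trace",
    "STATE_NAMES",
]

STATE_NAMES = {0: "unbound", 1: "moving", 2: "stalled", 3: "paused"}
_UNBOUND, _MOVING, _STALLED, _PAUSED = 0, 1, 2, 3


@dataclass
class TrapSimParams:
    """Trap/bead parameters.

    Defaults follow a single-bead trapping geometry: stiffness in the
    0.05-0.06 pN/nm operating range, drag of an 800-nm polystyrene bead
    near a surface (~1.2e-5 pN s/nm), acquisition at 5 kHz.
    """

    trap_stiffness: float = 0.055  # pN/nm
    drag_coefficient: float = 1.2e-5  # pN s/nm
    temperature: float = 296.0  # K
    sampling_rate: float = 5000.0  # Hz
    duration: float = 30.0  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trap_stiffness <= 0:
            raise ValueError("trap_stiffness must be positive")
        if self.drag_coefficient <= 0:
            raise ValueError("drag_coefficient must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive (time step must be positive)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class MotorModelParams:
    """Phenomenological motor model.

    ``unloaded_velocity`` and the detachment-force distribution set the
    ramp rate and stall level; ``force_velocity_exponent`` shapes the
    force-velocity curve.  ``pause_probability_per_s`` > 0 enables
    mutant-mode pausing inside ``pause_force_band``.  ``snap_back_present``
    controls whether a stall terminates with detachment and an
    instantaneous return of the tether to the trap center; when False the
    motor remains engaged at the stall plateau.
    """

    unloaded_velocity: float = 800.0  # nm/s
    detachment_force_mean: float = 4.0  # pN
    detachment_force_sd: float = 0.5  # pN
    force_velocity_exponent: float = 1.0
    pause_probability_per_s: float = 0.0  # 1/s, mutant mode when > 0
    pause_force_band: tuple[float, float] = (1.0, 2.0)  # pN
    pause_duration_mean: float = 0.5  # s
    snap_back_present: bool = True
    stall_duration_mean: float = 0.5  # s, exponential dwell at the plateau
    rebinding_time_mean: float = 0.5  # s, exponential unbound dwell
    pause_detach_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.detachment_force_mean <= 0:
            raise ValueError("detachment_force_mean must be positive")
        if self.pause_force_band[0] >= self.pause_force_band[1]:
            raise ValueError("pause_force_band must be an increasing interval")
        if self.unloaded_velocity < 0:
            raise ValueError("unloaded_velocity must be non-negative")


@dataclass
class TrueEvent:
    kind: str  # stall | pause | detachment
    start: float
    end: float
    force_at_event: float


@dataclass
class TrueEventLog:
    """Ground truth emitted by :func:`simulate_bead_trace`."""

    events: list[TrueEvent] = field(default_factory=list)
    motor_state_per_sample: np.ndarray = field(default_factory=lambda: np.empty(0, np.int8))
    state_names: dict[int, str] = field(default_factory=lambda: dict(STATE_NAMES))

    def of_kind(self, kind: str) -> list[TrueEvent]:
        return [e for e in self.events if e.kind == kind]

    def fraction_attached_in_band(
        self, trace: ForceTrace, band: tuple[float, float]
    ) -> float:
        """Fraction of attached samples whose force lies inside ``band``."""
        attached = self.motor_state_per_sample != _UNBOUND
        if not attached.any():
            return 0.0
        f = np.abs(trace.force[attached])
        return float(np.mean((f >= band[0]) & (f <= band[1])))


def _ou_coefficients(params: TrapSimParams) -> tuple[float, float]:
    """(decay per step ``a``, innovation sd) of the exact discrete OU update."""
    dt = 1.0 / params.sampling_rate
    tau = params.drag_coefficient / params.trap_stiffness
    a = float(np.exp(-dt / tau))
    var = BOLTZMANN_PN_NM * params.temperature / params.trap_stiffness
    return a, float(np.sqrt(var * (1.0 - a * a)))


def simulate_ou_bead(params: TrapSimParams) -> ForceTrace:
    """Bead in a static trap: exact OU position series, force = kappa * x.

    The initial condition is x = 0 (the trap center); with the default
    microsecond-scale relaxation time the series is stationary within
    the first few samples.  At zero temperature the position is
    identically zero.
    """
    n = int(round(params.duration * params.sampling_rate))
    a, innov_sd = _ou_coefficients(params)
    if params.temperature == 0.0:
        x = np.zeros(n)
    else:
        rng = np.random.default_rng(params.seed)
        innovations = rng.normal(0.0, innov_sd, n)
        x = lfilter([1.0], [1.0, -a], innovations)
    metadata = {
        "seed": params.seed,
        "true_trap_stiffness_pn_per_nm": params.trap_stiffness,
        "drag_coefficient_pn_s_per_nm": params.drag_coefficient,
        "temperature_k": params.temperature,
    }
    return ForceTrace.from_position(
        x, params.sampling_rate, params.trap_stiffness, metadata
    )


def simulate_bead_trace(
    trap: TrapSimParams, motor: MotorModelParams
) -> tuple[ForceTrace, TrueEventLog]:
    """Motor-driven bead trace plus ground-truth event log.

    Emits a warning (and no pauses) if mutant-mode pausing is requested
    with a pause band the motor cannot reach.
    """
    rng = np.random.default_rng(trap.seed)
    n = int(round(trap.duration * trap.sampling_rate))
    dt = 1.0 / trap.sampling_rate
    kappa = trap.trap_stiffness
    a, innov_sd = _ou_coefficients(trap)
    noise = rng.normal(0.0, innov_sd, n) if trap.temperature > 0 else np.zeros(n)
    pause_uniforms = rng.random(n)

    pause_enabled = motor.pause_probability_per_s > 0
    if pause_enabled:
        # force reachable while attached is bounded by ~detachment force
        reachable = motor.detachment_force_mean + 3 * motor.detachment_force_sd
        if motor.pause_force_band[0] > reachable:
            warnings.warn(
                "pause_force_band lies above the reachable force range; "
                "no pauses will be emitted",
                stacklevel=2,
            )
            pause_enabled = False
    p_pause_dt = motor.pause_probability_per_s * dt

    x = np.empty(n)
    states = np.empty(n, dtype=np.int8)
    log = TrueEventLog()

    def sample_f_detach() -> float:
        return max(0.5, rng.normal(motor.detachment_force_mean, motor.detachment_force_sd))

    state = _MOVING
    m = 0.0  # tether (motor) position, nm
    xi = 0.0
    f_detach = sample_f_detach()
    stall_start = 0.0
    until = np.inf  # end time of the current stalled/paused/unbound dwell
    pause_start = 0.0
    pause_force = 0.0
    v0 = motor.unloaded_velocity
    w = motor.force_velocity_exponent
    stall_trigger = 0.98

    for i in range(n):
        t = i * dt
        if state == _MOVING:
            f_tether = kappa * m
            in_band = motor.pause_force_band[0] <= f_tether <= motor.pause_force_band[1]
            if pause_enabled and in_band and pause_uniforms[i] < p_pause_dt:
                state = _PAUSED
                pause_start = t
                pause_force = f_tether
                until = t + rng.exponential(motor.pause_duration_mean)
            else:
                v = v0 * max(0.0, 1.0 - f_tether / f_detach) ** w
                m += v * dt
                if kappa * m >= stall_trigger * f_detach and v0 > 0:
                    state = _STALLED
                    m = f_detach / kappa  # motor holds at the stall plateau
                    stall_start = t
                    until = t + rng.exponential(motor.stall_duration_mean)
        elif state == _STALLED:
            if motor.snap_back_present and t >= until:
                log.events.append(TrueEvent("stall", stall_start, t, f_detach))
                log.events.append(TrueEvent("detachment", t, t, f_detach))
                m = 0.0  # snap back: tether returns to trap center
                state = _UNBOUND
                until = t + rng.exponential(motor.rebinding_time_mean)
        elif state == _PAUSED:
            if t >= until:
                log.events.append(TrueEvent("pause", pause_start, t, pause_force))
                if rng.random() < motor.pause_detach_probability:
                    log.events.append(TrueEvent("detachment", t, t, pause_force))
                    m = 0.0
                    state = _UNBOUND
                    until = t + rng.exponential(motor.rebinding_time_mean)
                else:
                    state = _MOVING
        else:  # unbound
            if t >= until:
                state = _MOVING
                m = xi  # reattach with a relaxed tether at the bead position
                f_detach = sample_f_detach()
        xi = m + (xi - m) * a + noise[i]
        x[i] = xi
        states[i] = state

    # close any stall still open at the end of the trace
    if state == _STALLED:
        log.events.append(TrueEvent("stall", stall_start, n * dt, f_detach))

    log.motor_state_per_sample = states
    metadata = {
        "seed": trap.seed,
        "true_trap_stiffness_pn_per_nm": kappa,
        "drag_coefficient_pn_s_per_nm": trap.drag_coefficient,
        "temperature_k": trap.temperature,
        "motor": {
            "unloaded_velocity_nm_per_s": motor.unloaded_velocity,
            "detachment_force_mean_pn": motor.detachment_force_mean,
            "detachment_force_sd_pn": motor.detachment_force_sd,
            "pause_probability_per_s": motor.pause_probability_per_s,
        },
    }
    trace = ForceTrace.from_position(x, trap.sampling_rate, kappa, metadata)
    return trace, log
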