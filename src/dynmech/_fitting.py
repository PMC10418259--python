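"""Least-squares Gaussian-sum fits to binned densities.

Both the trap force-sampling histogram and the angular-orientation
histograms are fitted the same way: a sum of Gaussians is fitted to the
*binned, normalized* density (not by expectation-maximization on the
raw samples), initialized from the highest local maxima of a lightly
smoothed copy of the histogram.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit

__all__ = ["GaussianComponent", "fit_gaussian_sum", "gaussian_sum"]

from dataclasses import dataclass


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return (
            self.weight
            / (self.sd * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * ((x - self.mean) / self.sd) ** 2)
        )


def gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    """Density of a weighted Gaussian sum; params = (w1, m1, s1, w2, ...)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for i in range(0, len(params), 3):
        w, m, s = params[i : i + 3]
        out += w / (s * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((x - m) / s) ** 2)
    return out


def _initial_guess(
    centers: np.ndarray, density: np.ndarray, n_components: int, smooth_bins: float
) -> list[float]:
    smoothed = gaussian_filter1d(density, smooth_bins, mode="nearest")
    interior = (
        (smoothed >= np.roll(smoothed, 1))
        & (smoothed >= np.roll(smoothed, -1))
        & (smoothed > 0)
    )
    interior[0] = smoothed[0] > smoothed[1]
    interior[-1] = smoothed[-1] > smoothed[-2]
    peaks = np.flatnonzero(interior)
    peaks = peaks[np.argsort(smoothed[peaks])[::-1]]
    bin_width = centers[1] - centers[0] if centers.size > 1 else 1.0
    means = [centers[p] for p in peaks[:n_components]]
    while len(means) < n_components:
        # fall back to mass quantiles for missing peaks
        mass = np.cumsum(density)
        mass = mass / mass[-1]
        q = (len(means) + 0.5) / n_components
        means.append(centers[np.searchsorted(mass, q)])
    span = max(centers[-1] - centers[0], bin_width)
    sd0 = max(2.0 * bin_width, span / (8.0 * n_components))
    total_mass = float(np.sum(density) * bin_width)
    p0: list[float] = []
    for m in means:
        p0 += [total_mass / n_components, float(m), sd0]
    return p0


def fit_gaussian_sum(
    centers: np.ndarray,
    density: np.ndarray,
    n_components: int,
    smooth_bins: float = 2.0,
) -> list[GaussianComponent]:
    """Fit ``n_components`` Gaussians to a binned density.

    Raises RuntimeError with the initialization in the message when the
    optimizer fails to converge.
    """
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    p0 = _initial_guess(centers, density, n_components, smooth_bins)
    span = max(centers[-1] - centers[0], 1e-9)
    bin_width = centers[1] - centers[0] if centers.size > 1 else 1.0
    lower = [0.0, centers[0] - span, bin_width / 10.0] * n_components
    upper = [np.inf, centers[-1] + span, 2.0 * span] * n_components
    try:
        popt, _ = curve_fit(
            gaussian_sum, centers, density, p0=p0,
            bounds=(lower, upper), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian-sum fit did not converge (n={n_components}, init={p0})"
        ) from exc
    comps = [
        GaussianComponent(weight=popt[i], mean=popt[i + 1], sd=popt[i + 2])
        for i in range(0, len(popt), 3)
    ]
    return sorted(comps, key=lambda c: c.mean)
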