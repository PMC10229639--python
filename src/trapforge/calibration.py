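"""Trap stiffness calibration from bead-only records.

A trapped microsphere behaves as if attached to a linear spring, so by
equipartition the positional variance of a bead-only record gives the
stiffness directly: k = kT / <x^2>.  The positional histogram of the same
record visualizes the (Gaussian) energy well, which narrows as stiffness
increases.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import thermal_energy
from .trace import Trace


@dataclass
class StiffnessEstimate:
    k_trap_hat: float   # pN/nm
    variance: float     # nm^2 (unbiased, mean-subtracted)
    n_samples: int
    temperature_K: float

    def to_dict(self) -> dict:
        return {"k_trap_hat": self.k_trap_hat, "variance": self.variance,
                "n": self.n_samples, "temperature_K": self.temperature_K}


def equipartition_stiffness(trace: Trace) -> StiffnessEstimate:
    """Estimate trap stiffness as kT over the positional variance.

    The caller is responsible for passing a bead-only record: binding
    events inflate the variance and bias the estimate low.  The sample
    mean is subtracted first, so a constant offset of the trap center
    does not affect the estimate.
    """
    x = trace.positions
    if x.size < 2:
        raise ValueError("need at least 2 samples for a variance")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        raise ValueError("degenerate trace: zero positional variance")
    kT = thermal_energy(trace.temperature_K)
    return StiffnessEstimate(kT / var, var, x.size, trace.temperature_K)


def positional_pdf(trace: Trace, bin_width: float = 1.0):
    """Normalized positional density of a record.

    Returns ``(centers, density)`` with ``sum(density) * bin_width == 1``.
    For a bead-only record this approximates a Gaussian of variance
    kT/k_trap centered on the trap center.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = trace.positions
    if x.size == 0:
        raise ValueError("empty trace")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    density, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def fit_gaussian_pdf(centers: np.ndarray, density: np.ndarray):
    """Least-squares Gaussian fit to a positional density.

    Returns ``(mu, sigma)``; used as an internal-consistency check that
    the well is harmonic.
    """

    def gauss(x, mu, sigma, amp):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    amp0 = density.max()
    mu0 = centers[np.argmax(density)]
    sigma0 = max((centers.max() - centers.min()) / 6.0, 1e-6)
    popt, _ = curve_fit(gauss, centers, density, p0=[mu0, sigma0, amp0],
                        maxfev=10000)
    return popt[0], abs(popt[1])
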