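"""Surface-density geometry from single-molecule localizations.

Motor positions on the coverslip (2-D localization coordinates from
super-resolution imaging) give a nearest-neighbor spacing; combined with
the pedestal-bead geometry — an actin filament touching a bead of radius
R can be reached by motors within ``reach`` of the surface, i.e. along a
chord of length 2*sqrt(2*R*h - h^2) at sagitta h = reach — this yields
the number of heads able to interact with the filament.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

DEFAULT_BEAD_RADIUS_NM = 1500.0
DEFAULT_REACH_NM = 20.0


def nearest_neighbor_distances(points) -> np.ndarray:
    """Distance from every point to its closest other point.

    ``points`` is an (n, 2) array of coordinates in nm, n >= 2.
    Coincident points yield distance 0 (with a warning).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n>=2, 2) coordinate array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    nn = dists[:, 1]
    if np.any(nn == 0):
        warnings.warn("coincident localizations: zero nearest-neighbor distance",
                      RuntimeWarning)
    return nn


def _freedman_diaconis_width(x: np.ndarray) -> float:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    w = 2.0 * iqr / np.cbrt(x.size)
    return w if w > 0 else max(np.ptp(x) / 10.0, 1.0)


def fit_nn_center(distances, bin_width: float | None = None) -> float:
    """Center of the nearest-neighbor distance histogram by Gaussian fit.

    Bins use the Freedman-Diaconis width unless given.  If the fit fails
    to converge the sample median is returned with a warning.
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 50:
        raise ValueError("need >= 50 distances for a stable histogram fit")
    if bin_width is None:
        bin_width = _freedman_diaconis_width(x)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(x.min(), x.max() + bin_width, bin_width)
    if edges.size < 4:
        edges = np.linspace(x.min(), x.max(), 5)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(v, mu, sigma, amp):
        return amp * np.exp(-0.5 * ((v - mu) / sigma) ** 2)

    try:
        popt, _ = curve_fit(gauss, centers, counts,
                            p0=[float(np.mean(x)), float(np.std(x) or 1.0),
                                float(counts.max())],
                            maxfev=10000)
        center = float(popt[0])
        if not (x.min() - bin_width <= center <= x.max() + bin_width):
            raise RuntimeError("fitted center outside the data range")
        return center
    except RuntimeError:
        warnings.warn("Gaussian fit did not converge; falling back to the "
                      "sample median", RuntimeWarning)
        return float(np.median(x))


def accessible_length(bead_radius_nm: float = DEFAULT_BEAD_RADIUS_NM,
                      reach_nm: float = DEFAULT_REACH_NM) -> float:
    """Chord length of the filament within motor reach of the pedestal.

    For a filament touching a bead of radius R, the part of the surface
    within height h of the filament spans a chord 2*sqrt(2*R*h - h^2).
    """
    if not (0 < reach_nm < bead_radius_nm):
        raise ValueError("need 0 < reach < bead radius")
    return 2.0 * np.sqrt(2.0 * bead_radius_nm * reach_nm - reach_nm ** 2)


@dataclass
class ReachEstimate:
    nn_center: float          # nm
    accessible_length: float  # nm
    heads_in_reach: float     # accessible_length / nn_center (1-D spacing)
    heads_in_reach_2d: float  # area-density alternative estimate

    def to_dict(self) -> dict:
        return asdict(self)


def heads_in_reach(points, bead_radius_nm: float = DEFAULT_BEAD_RADIUS_NM,
                   reach_nm: float = DEFAULT_REACH_NM,
                   bin_width: float | None = None,
                   reach_band_nm: float = 30.0) -> ReachEstimate:
    """Estimate how many surface motors can reach the filament.

    Primary estimate: accessible chord length divided by the fitted
    nearest-neighbor spacing (heads per filament length).  The 2-D
    variant multiplies the localization area density by the accessible
    chord times a ``reach_band_nm``-wide lateral capture band.
    """
    pts = np.asarray(points, dtype=float)
    nn = nearest_neighbor_distances(pts)
    center = fit_nn_center(nn, bin_width)
    length = accessible_length(bead_radius_nm, reach_nm)
    area = np.ptp(pts[:, 0]) * np.ptp(pts[:, 1])
    density = pts.shape[0] / area if area > 0 else np.nan
    return ReachEstimate(
        nn_center=center,
        accessible_length=length,
        heads_in_reach=length / center,
        heads_in_reach_2d=float(density * length * reach_band_nm),
    )
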