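"""Bell-bond fitting of load-dependent detachment rates.

The Bell model k_det(F) = k0 * exp(F*d/kT) describes how a resistive
force F tilts the energy landscape of a bond: d (nm) is the distance to
the transition state, the slope of ln k against F in units of kT.  A
positive d means load accelerates detachment (slip); a negative d means
load slows it (catch-like), as for the ADP-release-limited pathway.

Fitting is weighted nonlinear least squares in the (ln k0, d)
parameterization, seeded by the exact log-linear solution; with 1/SEM^2
weights the parameter covariance is taken at the stated SEMs
(absolute sigma), otherwise it is scaled by the residual variance.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy

_Z95 = 1.959963984540054


def bell_rate(k0: float, d: float, F, kT: float):
    """Detachment rate k0 * exp(F*d/kT); scalar or array in F."""
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if kT <= 0:
        raise ValueError("kT must be positive")
    expo = np.asarray(F, dtype=float) * d / kT
    if np.any(np.abs(expo) > 700):
        raise OverflowError("Bell exponent magnitude exceeds 700")
    out = k0 * np.exp(expo)
    return float(out) if out.ndim == 0 else out


@dataclass
class BellPoint:
    """One condition-level point: mean peak force and detachment rate.

    ``sem_F`` (optional) is the standard error of the mean force; when
    given it enters the fit through the effective-variance scheme, since
    condition means carry sampling noise on both axes.
    """

    F: float        # pN
    k_det: float    # 1/s
    sem_k: float = 0.0
    n_events: int = 1
    sem_F: float = 0.0

    def __post_init__(self) -> None:
        if self.k_det <= 0:
            raise ValueError("k_det must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass
class BellFit:
    k0: float
    d: float
    se_k0: float
    se_d: float
    ci95_k0: tuple
    ci95_d: tuple
    kT: float
    n_points: int
    rss: float
    weighted: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95_k0"] = list(self.ci95_k0)
        d["ci95_d"] = list(self.ci95_d)
        return d

    def predict(self, F):
        return bell_rate(self.k0, self.d, F, self.kT)


def fit_bell(points, temperature_K: float = DEFAULT_TEMPERATURE_K,
             weighted: bool | None = None) -> BellFit:
    """Fit (k0, d) to condition-level (F, k_det) points.

    ``weighted`` defaults to using 1/SEM^2 weights when every point has a
    positive SEM, unweighted otherwise.  When force SEMs are supplied the
    weights use the effective variance sem_k^2 + (dk/dF)^2 sem_F^2
    (one re-weighting pass at the fitted slope), the standard treatment
    for regression with errors in both variables.  Standard errors come
    from the Jacobian at the optimum; 95% CIs are normal-theory
    +/- 1.96 SE.  Needs >= 3 points with at least two distinct forces.
    """
    points = list(points)
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit the Bell equation")
    F = np.array([p.F for p in points], dtype=float)
    k = np.array([p.k_det for p in points], dtype=float)
    sems = np.array([p.sem_k for p in points], dtype=float)
    sems_F = np.array([p.sem_F for p in points], dtype=float)
    if np.ptp(F) == 0:
        raise ValueError("all forces identical: (k0, d) not identifiable")
    if weighted is None:
        weighted = bool(np.all(sems > 0))
    kT = thermal_energy(temperature_K)

    # exact log-linear start: ln k = ln k0 + F d / kT
    A = np.column_stack([np.ones_like(F), F / kT])
    theta0, *_ = np.linalg.lstsq(A, np.log(k), rcond=None)

    def solve(sigma):
        def resid(theta):
            return (np.exp(theta[0] + F * theta[1] / kT) - k) / sigma

        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                            gtol=1e-14, max_nfev=1000 * (len(points) + 2))
        if not sol.success:
            raise RuntimeError(f"Bell fit did not converge: {sol.message}; "
                               f"best loss {0.5 * np.sum(sol.fun ** 2)}")
        return sol

    sigma = sems if weighted else np.ones_like(k)
    sol = solve(sigma)
    if weighted and np.any(sems_F > 0):
        slope = np.exp(sol.x[0] + F * sol.x[1] / kT) * sol.x[1] / kT  # dk/dF
        sigma = np.sqrt(sems ** 2 + (slope * sems_F) ** 2)
        sol = solve(sigma)
    lnk0, d = sol.x
    J = sol.jac
    dof = max(len(points) - 2, 1)
    rss = float(np.sum(sol.fun ** 2))
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J)
    if not weighted:
        cov = cov * rss / dof  # scale by residual variance
    se_lnk0, se_d = np.sqrt(np.maximum(np.diag(cov), 0.0))
    k0 = float(np.exp(lnk0))
    se_k0 = k0 * se_lnk0  # delta method
    return BellFit(
        k0=k0, d=float(d), se_k0=float(se_k0), se_d=float(se_d),
        ci95_k0=(k0 - _Z95 * se_k0, k0 + _Z95 * se_k0),
        ci95_d=(float(d - _Z95 * se_d), float(d + _Z95 * se_d)),
        kT=kT, n_points=len(points), rss=rss, weighted=weighted,
    )


def fit_bell_bootstrap(metrics_by_condition: dict, temperature_K: float,
                       n_boot: int = 2000, seed: int = 0) -> dict:
    """Bootstrap-over-events 95% CIs for (k0, d).

    ``metrics_by_condition`` maps a condition key to arrays
    ``(peak_forces, t_pf)`` of the per-event measurements.  Each
    replicate resamples events within every condition, rebuilds the
    condition points (mean F, 1/mean T_PF) and refits.
    """
    rng = np.random.default_rng(seed)
    k0s, ds = [], []
    for _ in range(n_boot):
        pts = []
        for (Fs, tpfs) in metrics_by_condition.values():
            Fs = np.asarray(Fs, dtype=float)
            tpfs = np.asarray(tpfs, dtype=float)
            idx = rng.integers(0, Fs.size, Fs.size)
            pts.append(BellPoint(float(Fs[idx].mean()),
                                 1.0 / float(tpfs[idx].mean()),
                                 n_events=Fs.size))
        try:
            fit = fit_bell(pts, temperature_K, weighted=False)
        except (ValueError, RuntimeError):
            continue
        k0s.append(fit.k0)
        ds.append(fit.d)
    k0s, ds = np.array(k0s), np.array(ds)
    return {
        "ci95_k0": list(np.percentile(k0s, [2.5, 97.5])),
        "ci95_d": list(np.percentile(ds, [2.5, 97.5])),
        "n_successful": int(k0s.size),
    }


def compare_fits(fit_a: BellFit, fit_b: BellFit) -> dict:
    """95% CI overlap report for two fits, plus the d ratio (b/a)."""

    def overlap(ci1, ci2):
        return bool(ci1[0] <= ci2[1] and ci2[0] <= ci1[1])

    k0_overlap = overlap(fit_a.ci95_k0, fit_b.ci95_k0)
    d_overlap = overlap(fit_a.ci95_d, fit_b.ci95_d)
    return {
        "k0_ci_overlap": k0_overlap,
        "d_ci_overlap": d_overlap,
        "k0_significantly_different": not k0_overlap,
        "d_significantly_different": not d_overlap,
        "d_ratio": float(fit_b.d / fit_a.d) if fit_a.d != 0 else np.inf,
        "k0_ratio": float(fit_b.k0 / fit_a.k0),
    }
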