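"""Desk-scale experiments exercising the whole pipeline.

These are the canonical self-checks of the package, shared by the
analysis drivers, the acceptance tests and ``scripts/acceptance.py``:
parameter-recovery runs of simulator -> detector -> features -> Bell fit
under the study conditions (trap stiffnesses 0.04/0.06/0.10 pN/nm,
5 kHz sampling, 30 mM Pi for the slip-pathway runs), plus the exact
geometric/arithmetic reproductions (derived head-count table, pedestal
reach geometry).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .bell import BellPoint, bell_rate, fit_bell
from .calibration import equipartition_stiffness
from .config import SimConfig
from .constants import thermal_energy
from .detect import detect_events, match_events
from .ensemble_table import (heads_from_displacement, force_from_displacement,
                             round_half_up, round_sig)
from .features import event_metrics, summarize_condition
from .simulate import (simulate_bead_only, simulate_ensemble_trace,
                       simulate_event_metrics)
from .storm import accessible_length

STIFFNESSES = (0.04, 0.06, 0.10)

#: study condition for the load-dependence recovery runs: pure
#: Pi-induced detachment with the mutant-like parameters (unloaded rate
#: 2.5 1/s at 30 mM, distance 4.1 nm)
SLIP_TRUTH = {"k_pi0_per_mM": 2.5 / 30.0, "d_pi": 4.1, "pi_mM": 30.0,
              "k_adp0": 0.0}


def slip_config(k_trap: float, duration_s: float, seed: int) -> SimConfig:
    return SimConfig(k_trap=k_trap, duration_s=duration_s, seed=seed,
                     **SLIP_TRUTH)


def equipartition_recovery(seed: int, duration_s: float = 10.0) -> dict:
    """Bead-only records at the three stiffnesses; returns recovery errors."""
    out = {}
    for i, k in enumerate(STIFFNESSES):
        cfg = SimConfig(k_trap=k, duration_s=duration_s, seed=seed + i)
        est = equipartition_stiffness(simulate_bead_only(cfg))
        out[k] = {"k_hat": est.k_trap_hat, "variance": est.variance,
                  "rel_err": est.k_trap_hat / k - 1.0, "n": est.n_samples}
    return out


def bell_exact_recovery() -> dict:
    """Noiseless-point recovery of reference (k0, d) pairs."""
    worst = 0.0
    cases = [(2.5, 4.1, (1.65, 1.74, 2.34)),   # mutant-like slip pathway
             (13.7, 0.6, (1.0, 2.2, 4.0)),     # WT-like slip pathway
             (16.8, -0.9, (1.2, 1.6, 2.8))]    # catch pathway
    kT = thermal_energy()
    for k0, d, forces in cases:
        pts = [BellPoint(F, bell_rate(k0, d, F, kT)) for F in forces]
        fit = fit_bell(pts)
        worst = max(worst, abs(fit.k0 / k0 - 1.0), abs((fit.d - d) / d))
    return {"max_rel_err": worst, "n_cases": len(cases)}


def detector_benchmark(seed: int, seeds_per_pool: int = 3,
                       duration_s: float = 60.0, width: int = 100) -> dict:
    """Recall/precision/boundary accuracy pooled over seeded simulations.

    Recall is scored on truth events at least two window widths long
    (shorter events carry a mean shift that never spans a full window);
    the simulated ensembles shift the mean by ~28 nm against a ~10 nm
    baseline SD.  Boundary error pools both ends of every matched pair.
    """
    total_big = matched_big = total_det = matched_all = 0
    errors = []
    for s in range(seeds_per_pool):
        cfg = slip_config(0.04, duration_s, seed + s)
        trace, truth = simulate_ensemble_trace(cfg)
        events = detect_events(trace, seed=seed)
        pairs, _, _ = match_events(events, truth.events)
        big = {i for i, e in enumerate(truth.events) if e.n_samples >= 2 * width}
        total_big += len(big)
        matched_big += sum(1 for i, _ in pairs if i in big)
        total_det += len(events)
        matched_all += len(pairs)
        for i, j in pairs:
            errors.append(abs(events[j].start_sample
                              - truth.events[i].start_sample))
            errors.append(abs(events[j].end_sample
                              - truth.events[i].end_sample))
    return {
        "recall": matched_big / total_big if total_big else float("nan"),
        "precision": matched_all / total_det if total_det else float("nan"),
        "boundary_median_err": float(np.median(errors)) if errors else float("nan"),
        "n_truth_events": total_big,
        "n_detected": total_det,
    }


def pipeline_bell_points(seed: int, duration_s: float = 400.0) -> list[BellPoint]:
    """Full simulate->detect->features chain at each stiffness."""
    pts = []
    for i, k in enumerate(STIFFNESSES):
        cfg = slip_config(k, duration_s, seed + 101 * i)
        trace, _ = simulate_ensemble_trace(cfg)
        events = detect_events(trace, seed=seed)
        m = event_metrics(trace, events)
        s = summarize_condition(m, ["k_trap"]).iloc[0]
        pts.append(BellPoint(s.peak_force_mean, s.k_det, s.k_det_sem,
                             int(s.n_events)))
    return pts


def end_to_end_recovery(seed: int, duration_s: float = 400.0) -> dict:
    """Pipeline estimate of the slip-pathway distance parameter."""
    pts = pipeline_bell_points(seed, duration_s)
    fit = fit_bell(pts)
    truth = SLIP_TRUTH["d_pi"]
    return {
        "d_hat": fit.d, "d_truth": truth,
        "rel_err": fit.d / truth - 1.0,
        "ci95_d": list(fit.ci95_d),
        "k0_hat": fit.k0,
        "n_events": sum(p.n_events for p in pts),
        "forces": [p.F for p in pts],
        "rates": [p.k_det for p in pts],
    }


def truth_bell_fit(seed: int, n_events: int = 500) -> "fit_bell":
    """Condition-level Bell fit from kinetics-only ground-truth events."""
    pts = []
    for i, k in enumerate(STIFFNESSES):
        cfg = slip_config(k, 1.0, seed)
        df = simulate_event_metrics(cfg, n_events, seed=seed + 101 * i)
        F = df.peak_force_pN
        t = df.t_pf
        n = len(df)
        sem_t = t.std(ddof=1) / np.sqrt(n)
        pts.append(BellPoint(float(F.mean()), 1.0 / float(t.mean()),
                             float(sem_t / t.mean() ** 2), n,
                             sem_F=float(F.std(ddof=1) / np.sqrt(n))))
    return fit_bell(pts)


def coverage_experiment(seed: int, n_seeds: int = 100,
                        n_events: int = 500) -> dict:
    """CI-calibration: how often the fit's 95% CI covers the generating d.

    Uses the kinetics-only event sampler (the noiseless measurement layer
    of the generator) so that one hundred replicates of 3 x n_events are
    feasible at the desk scale.
    """
    truth = SLIP_TRUTH["d_pi"]
    hits = 0
    d_hats = []
    for r in range(n_seeds):
        fit = truth_bell_fit(seed + 7919 * r, n_events)
        d_hats.append(fit.d)
        if fit.ci95_d[0] <= truth <= fit.ci95_d[1]:
            hits += 1
    return {"coverage": hits / n_seeds, "n_seeds": n_seeds,
            "d_hat_mean": float(np.mean(d_hats)),
            "d_hat_sd": float(np.std(d_hats))}


def directionality(seed: int, n_events: int = 500) -> dict:
    """Sign checks of the load dependence of mean lifetimes.

    With Pi and a slip distance, stiffer traps shorten events; without
    Pi (catch pathway), stiffer traps lengthen them.
    """
    res = {}
    for tag, overrides in [("pi30", {"pi_mM": 30.0, "k_adp0": 0.0}),
                           ("pi0", {"pi_mM": 0.0})]:
        t_on = {}
        for i, k in enumerate((0.04, 0.10)):
            cfg = SimConfig(k_trap=k, duration_s=1.0, seed=seed, **overrides)
            df = simulate_event_metrics(cfg, n_events, seed=seed + 31 * i)
            t_on[k] = float(df.t_on.mean())
        res[tag] = {"t_on_soft": t_on[0.04], "t_on_stiff": t_on[0.10],
                    "ratio": t_on[0.10] / t_on[0.04]}
    return res


# printed reference rows of the derived-columns table: construct, Pi (mM),
# k_trap, mean peak displacement (nm) -> printed force, heads
TABLE_ROWS = [
    ("WT", 0, 0.04, 29.1, 1.16, 4.2),
    ("WT", 0, 0.06, 26.5, 1.59, 3.8),
    ("WT", 0, 0.10, 28.2, 2.82, 4.0),
    ("WT", 30, 0.06, 36.2, 2.17, 5.2),
    ("WT", 30, 0.10, 40.2, 4.02, 5.7),
    ("S217A", 30, 0.06, 29.0, 1.74, 4.1),
    ("S217A", 30, 0.10, 23.4, 2.34, 3.3),
]


def table_arithmetic() -> pd.DataFrame:
    """Derived columns recomputed from the printed mean displacements."""
    rows = []
    for construct, pi, k, disp, _, _ in TABLE_ROWS:
        force = force_from_displacement(disp, k)
        heads = heads_from_displacement(disp)
        rows.append({
            "construct": construct, "pi_mM": pi, "k_trap": k,
            "displacement": disp,
            "force": round_sig(force, 3),
            "heads": round_half_up(heads, 1),
            "force_per_head": round_sig(force / heads, 2),
        })
    return pd.DataFrame(rows)


def reach_geometry() -> dict:
    """Pedestal chord geometry and heads-in-reach at the reported spacing."""
    chord = accessible_length(1500.0, 20.0)
    return {"chord_nm": chord, "nn_spacing_nm": 119.0,
            "heads_in_reach": chord / 119.0}
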