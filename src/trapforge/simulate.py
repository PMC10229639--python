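"""Synthetic mini-ensemble trap records.

The generator has two layers:

* an exact-discretization Ornstein-Uhlenbeck (OU) sampler for the
  overdamped Brownian motion of the trapped bead-actin-bead assembly
  (stationary variance kT/k, autocorrelation exp(-k*dt/gamma)), and
* a continuous-time Markov (Gillespie) simulation of myosin-head
  attachment/detachment whose piecewise-constant quasi-static mechanics
  modulate the OU mean and stiffness.

With N heads attached and cumulative powerstrokes S (nm), the equilibrium
bead position is ``mu = S * N*k_head / (k_trap + N*k_head)``, the ensemble
force is ``F = k_trap * mu``, and each attached head detaches with hazard

    h = k_adp0 * exp(-load * d_adp / kT) + pi_mM * k_pi0_per_mM * exp(+load * d_pi / kT)

where ``load`` is the resistive load on the head (the full F for
``load_sharing="total"``, F/N for ``"equal"``).  A binding event is a
maximal interval with at least one head attached.

Attachment has three mechanistic features of a surface mini-ensemble:
events initiate at the slow diffusive-encounter rate ``k_init``; once the
filament is held down, further heads bind cooperatively at ``k_attach``
each, Bell-suppressed by load (``d_attach``, the stall mechanism); and a
head that detaches is refractory (ADP.Pi must be processed and the lever
re-primed) until it recovers at ``k_recover`` or the ensemble fully
detaches.  Without the stall the chain is transient at pi_mM=0: the catch
pathway would let force ratchet up until detachment effectively stops.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import SimConfig
from .trace import GroundTruth, Trace, TrueEvent

_EXP_CLIP = 700.0


def _equilibrium_mean(S: float, N: int, k_trap: float, k_head: float) -> float:
    if N == 0:
        return 0.0
    k_ens = N * k_head
    return S * k_ens / (k_trap + k_ens)


def _detach_hazard(load: float, cfg: SimConfig, kT: float) -> float:
    """Per-attached-head detachment hazard at resistive load `load` (pN)."""
    e_adp = -load * cfg.d_adp / kT
    e_pi = load * cfg.d_pi / kT
    if abs(e_adp) > _EXP_CLIP or abs(e_pi) > _EXP_CLIP:
        warnings.warn("detachment hazard exponent clipped at +/-700", RuntimeWarning)
        e_adp = float(np.clip(e_adp, -_EXP_CLIP, _EXP_CLIP))
        e_pi = float(np.clip(e_pi, -_EXP_CLIP, _EXP_CLIP))
    return cfg.k_adp0 * np.exp(e_adp) + cfg.pi_mM * cfg.k_pi0_per_mM * np.exp(e_pi)


def _ou_segment(rng: np.random.Generator, n: int, mu: float, k_eff: float,
                cfg: SimConfig, x_prev: float) -> np.ndarray:
    """Sample n OU points after x_prev with mean mu and stiffness k_eff."""
    kT = cfg.kT
    a = np.exp(-k_eff * cfg.dt / cfg.gamma)
    sd = np.sqrt(kT / k_eff * (1.0 - a * a))
    z = rng.standard_normal(n)
    # AR(1) deviation y_i = a*y_{i-1} + sd*z_i seeded by the previous sample
    y, _ = lfilter([1.0], [1.0, -a], sd * z, zi=[a * (x_prev - mu)])
    return mu + y


def simulate_bead_only(config: SimConfig) -> Trace:
    """Simulate a bead-only record: stationary OU at the trap stiffness.

    The stationary variance is kT/k_trap (equipartition) and the lag-1
    autocorrelation exp(-k_trap*dt/gamma).  Deterministic under fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if n < 1:
        raise ValueError("duration too short for one sample")
    kT = config.kT
    x0 = rng.standard_normal() * np.sqrt(kT / config.k_trap)
    x = _ou_segment(rng, n, 0.0, config.k_trap, config, x0)
    return Trace(x, config.sample_rate_hz, config.k_trap, config.temperature_K,
                 condition=f"bead-only k={config.k_trap}")


@dataclass
class _Transition:
    time_s: float
    kind: str          # "attach" | "detach"
    n_after: int
    steps_after: float  # cumulative step displacement S, nm
    mean_after: float   # quasi-static mean bead position, nm


def _gillespie(config: SimConfig, rng: np.random.Generator, *,
               t_max: float | None = None,
               n_events: int | None = None) -> list[_Transition]:
    """Run the head attach/detach chain; stop at t_max or after n_events."""
    kT = config.kT
    t = 0.0
    N = 0          # heads attached
    R = 0          # heads refractory (detached, not yet competent to rebind)
    S = 0.0
    events_done = 0
    out: list[_Transition] = []
    while True:
        if t_max is not None and t >= t_max:
            break
        if n_events is not None and events_done >= n_events:
            break
        mu_now = _equilibrium_mean(S, N, config.k_trap, config.k_head)
        F_now = config.k_trap * mu_now
        if N == 0:
            # diffusive encounter of the filament with the motor field
            attach_rate = config.k_init if config.n_heads > 0 else 0.0
        else:
            e_att = -F_now * config.d_attach / kT
            attach_rate = ((config.n_heads - N - R) * config.k_attach
                           * np.exp(max(e_att, -_EXP_CLIP)))
        recover_rate = R * config.k_recover
        if N > 0:
            load = F_now if config.load_sharing == "total" else F_now / N
            detach_rate = N * _detach_hazard(load, config, kT)
        else:
            detach_rate = 0.0
        total = attach_rate + detach_rate + recover_rate
        if total <= 0.0:
            break  # absorbing (e.g. n_heads == 0)
        t += rng.exponential(1.0 / total)
        if t_max is not None and t >= t_max:
            break
        u = rng.random() * total
        if u < attach_rate:
            N += 1
            S += config.step_nm
        elif u < attach_rate + recover_rate:
            R -= 1
            continue  # internal transition: mechanics unchanged
        else:
            N -= 1
            R += 1
            if N == 0:
                S = 0.0
                R = 0  # full chemomechanical reset during the detached dwell
                events_done += 1
        kind = "attach" if u < attach_rate else "detach"
        out.append(_Transition(t, kind, N, S,
                               _equilibrium_mean(S, N, config.k_trap, config.k_head)))
    return out


def _truth_from_transitions(transitions: list[_Transition], config: SimConfig,
                            n_samples: int) -> GroundTruth:
    """Round transitions to samples and build non-degenerate truth events."""
    events: list[TrueEvent] = []
    current: list[_Transition] = []
    for tr in transitions:
        current.append(tr)
        if tr.kind == "detach" and tr.n_after == 0:
            start = int(round(current[0].time_s * config.sample_rate_hz))
            end = int(round(tr.time_s * config.sample_rate_hz))
            start = max(0, min(start, n_samples))
            end = max(0, min(end, n_samples))
            if end > start:  # sub-sample events are dropped: undetectable
                events.append(TrueEvent(start, end,
                                        [(c.time_s, c.kind, c.n_after, c.mean_after)
                                         for c in current]))
            current = []
    # an event still open at record end is truncated at the last sample
    if current:
        start = int(round(current[0].time_s * config.sample_rate_hz))
        if start < n_samples:
            events.append(TrueEvent(start, n_samples,
                                    [(c.time_s, c.kind, c.n_after, c.mean_after)
                                     for c in current]))
    return GroundTruth(events)


def simulate_ensemble_trace(config: SimConfig) -> tuple[Trace, GroundTruth]:
    """Simulate a displacement record with stochastic binding events.

    Returns the painted trace and ground-truth annotations.  Transition
    times are rounded to the nearest sample when painting; events shorter
    than one sample are dropped from the truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if config.n_heads == 0:
        trace = simulate_bead_only(config)
        return trace, GroundTruth([])
    transitions = _gillespie(config, rng, t_max=config.duration_s)
    truth = _truth_from_transitions(transitions, config, n)

    # piecewise-constant (mu, k_eff) per inter-transition segment
    bounds = [0]
    params: list[tuple[float, float]] = []
    N, S = 0, 0.0
    for tr in transitions:
        s = int(round(tr.time_s * config.sample_rate_hz))
        s = max(0, min(s, n))
        if s > bounds[-1]:
            params.append((_equilibrium_mean(S, N, config.k_trap, config.k_head),
                           config.k_trap + N * config.k_head))
            bounds.append(s)
        N, S = tr.n_after, tr.steps_after
    if bounds[-1] < n:
        params.append((_equilibrium_mean(S, N, config.k_trap, config.k_head),
                       config.k_trap + N * config.k_head))
        bounds.append(n)

    kT = config.kT
    x = np.empty(n)
    x_prev = rng.standard_normal() * np.sqrt(kT / config.k_trap)
    for (mu, k_eff), lo, hi in zip(params, bounds[:-1], bounds[1:]):
        seg = _ou_segment(rng, hi - lo, mu, k_eff, config, x_prev)
        x[lo:hi] = seg
        x_prev = seg[-1]
    cond = f"sim k={config.k_trap} pi={config.pi_mM}"
    trace = Trace(x, config.sample_rate_hz, config.k_trap, config.temperature_K, cond)
    return trace, truth


def simulate_event_metrics(config: SimConfig, n_events: int,
                           seed: int | None = None) -> pd.DataFrame:
    """Kinetics-only event sampler: ground-truth metrics without trace painting.

    Runs the Gillespie chain until `n_events` complete binding events and
    returns one row per event with the noiseless analogues of the measured
    quantities: lifetime ``t_on``, peak quasi-static displacement
    ``peak_nm``, peak ensemble force ``peak_force_pN`` and the time from
    the onset of the maximal displacement plateau to detachment ``t_pf``.
    Useful for calibration/coverage experiments where painting and
    re-detecting millions of samples would add nothing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    transitions = _gillespie(config, rng, n_events=n_events)
    rows = []
    current: list[_Transition] = []
    t_prev_end = 0.0
    for tr in transitions:
        current.append(tr)
        if tr.kind == "detach" and tr.n_after == 0:
            t_start = current[0].time_s
            t_end = tr.time_s
            mus = np.array([c.mean_after for c in current])
            peak = mus.max()
            i_peak = int(np.argmax(mus))  # earliest maximal plateau
            t_peak = current[i_peak].time_s
            rows.append({
                "t_start": t_start,
                "t_on": t_end - t_start,
                "wait_s": t_start - t_prev_end,
                "peak_nm": peak,
                "peak_force_pN": config.k_trap * peak,
                "t_pf": t_end - t_peak,
                "n_steps": len([c for c in current if c.kind == "attach"]),
            })
            t_prev_end = t_end
            current = []
    return pd.DataFrame(rows)
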