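"""Per-event mechanics: peak displacement/force, time at peak force, rates.

For each binding event the peak displacement is the largest mean of a
sliding 5 ms window inside the event, the peak force is the trap
stiffness times that displacement, and the time at peak force (T_PF)
runs from the start of the maximal window to the event end.  1/T_PF
estimates the detachment rate under the peak load, which is what the
Bell-bond fit consumes at the condition level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .detect import DetectedEvent
from .trace import Trace

logger = logging.getLogger(__name__)

PEAK_WINDOW_MS = 5.0


@dataclass
class EventMetrics:
    event_id: int
    t_on: float             # s
    peak_displacement: float  # nm
    peak_force: float       # pN
    t_pf: float             # s
    k_det: float            # 1/s
    k_trap: float           # pN/nm
    condition: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def peak_window(trace: Trace, event: DetectedEvent,
                window_ms: float = PEAK_WINDOW_MS) -> tuple[float, int]:
    """Largest sustained displacement: max running mean over `window_ms`.

    Slides a window of ``round(window_ms * rate / 1000)`` samples one
    sample at a time over the event and returns ``(peak, start_sample)``
    of the maximal window, ties to the earliest.  An event shorter than
    the window is flagged and its overall mean returned.
    """
    w = max(1, int(round(window_ms * 1e-3 * trace.sample_rate_hz)))
    seg = trace.positions[event.start_sample:event.end_sample]
    if seg.size < w:
        logger.warning("event [%d,%d) shorter than the %d-sample peak window; "
                       "using the whole-event mean", event.start_sample,
                       event.end_sample, w)
        return float(seg.mean()), event.start_sample
    c = np.concatenate([[0.0], np.cumsum(seg)])
    sums = c[w:] - c[:-w]
    i = int(np.argmax(sums))  # argmax takes the earliest tie
    return float(sums[i] / w), event.start_sample + i


def time_at_peak_force(trace: Trace, event: DetectedEvent,
                       peak_start_sample: int) -> float:
    """T_PF: from the start of the maximal window to event termination."""
    if not (event.start_sample <= peak_start_sample < event.end_sample):
        raise ValueError("peak window start must lie within the event")
    t_pf = (event.end_sample - peak_start_sample) / trace.sample_rate_hz
    if t_pf <= 0:
        raise ValueError("zero-length time at peak force")
    return t_pf


def event_metrics(trace: Trace, events, window_ms: float = PEAK_WINDOW_MS,
                  k_trap: float | None = None,
                  condition: str | None = None) -> pd.DataFrame:
    """Compute EventMetrics rows for every detected event of one record.

    ``k_trap`` defaults to the trace metadata value (pass the calibrated
    estimate to use it instead).
    """
    k = trace.k_trap if k_trap is None else k_trap
    cond = trace.condition if condition is None else condition
    rows = []
    for i, ev in enumerate(events):
        peak, peak_start = peak_window(trace, ev, window_ms)
        t_pf = time_at_peak_force(trace, ev, peak_start)
        rows.append(EventMetrics(
            event_id=i,
            t_on=ev.t_on,
            peak_displacement=peak,
            peak_force=k * peak,
            t_pf=t_pf,
            k_det=1.0 / t_pf,
            k_trap=k,
            condition=cond,
        ).to_dict())
    return pd.DataFrame(rows, columns=["event_id", "t_on", "peak_displacement",
                                       "peak_force", "t_pf", "k_det", "k_trap",
                                       "condition"])


def summarize_condition(metrics: pd.DataFrame,
                        grouping=("condition", "k_trap")) -> pd.DataFrame:
    """Per-condition means and SEMs of the event metrics.

    The condition-level detachment rate is 1/mean(T_PF) (rate of the
    mean dwell, robust against short-dwell outliers in 1/T_PF); its SEM
    follows by first-order propagation, SEM(k) = SEM(T_PF)/mean(T_PF)^2.
    The mean of per-event rates is also reported as ``k_det_mean_of_rates``.
    A single-event group gets SEM 0 and ``sem_defined=False``.
    """
    grouping = list(grouping)
    rows = []
    for key, g in metrics.groupby(grouping):
        if len(g) == 0:
            logger.info("skipping empty group %s", key)
            continue
        n = len(g)
        sem_defined = n > 1

        def sem(x):
            return float(np.std(x, ddof=1) / np.sqrt(n)) if sem_defined else 0.0

        mean_tpf = float(g.t_pf.mean())
        row = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        row.update({
            "n_events": n,
            "t_on_mean": float(g.t_on.mean()), "t_on_sem": sem(g.t_on),
            "peak_displacement_mean": float(g.peak_displacement.mean()),
            "peak_displacement_sem": sem(g.peak_displacement),
            "peak_force_mean": float(g.peak_force.mean()),
            "peak_force_sem": sem(g.peak_force),
            "t_pf_mean": mean_tpf, "t_pf_sem": sem(g.t_pf),
            "k_det": 1.0 / mean_tpf,
            "k_det_sem": sem(g.t_pf) / mean_tpf ** 2,
            "k_det_mean_of_rates": float(g.k_det.mean()),
            "sem_defined": sem_defined,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities (ends at 1)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    return v, np.arange(1, v.size + 1) / v.size
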