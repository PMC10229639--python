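"""Binding-event detection in displacement records.

The record is reduced to running-window features (mean and variance over
100-sample windows advanced by a quarter window), a two-state Gaussian
HMM is fitted to (mean, log variance) by Baum-Welch, the Viterbi path
labels each window bound/unbound, maximal bound runs become coarse
events, and each coarse boundary is refined to the sample maximizing the
two-segment Gaussian likelihood in a neighborhood of two window widths.

Binding both shifts the window mean (the ensemble drags the bead) and
drops the window variance (extra stiffness from attached heads), so the
two features separate the regimes even when the mean shift alone is
modest.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .trace import Trace

logger = logging.getLogger(__name__)

#: floor added to window variances before taking logs
LOGVAR_EPS = 1e-6


@dataclass
class WindowFeatures:
    """Running mean/variance features on a fixed window grid."""

    starts: np.ndarray      # start sample of each window
    means: np.ndarray       # nm
    variances: np.ndarray   # nm^2, ddof=1
    width: int
    step: int

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def matrix(self) -> np.ndarray:
        """(n_windows, 2) feature matrix: mean and log(variance + eps)."""
        return np.column_stack([self.means, np.log(self.variances + LOGVAR_EPS)])


@dataclass
class HmmModel:
    """A fitted two-state model with the convention state 0 = unbound.

    The unbound state is the one with the larger emission mean of the
    log-variance feature (free bead -> broad Brownian motion).
    """

    means: np.ndarray        # (2, 2): rows states, cols (mean, logvar)
    variances: np.ndarray    # (2, 2) diagonal emission variances
    transmat: np.ndarray     # (2, 2), rows sum to 1
    startprob: np.ndarray
    log_likelihood: float
    degenerate: bool = False
    _hmm: GaussianHMM | None = field(default=None, repr=False)
    _order: np.ndarray | None = field(default=None, repr=False)

    def predict(self, features: WindowFeatures) -> np.ndarray:
        """Viterbi decode; returns 0 (unbound) / 1 (bound) per window."""
        if self.degenerate or self._hmm is None:
            return np.zeros(features.n_windows, dtype=int)
        raw = self._hmm.predict(features.matrix())
        return np.asarray(self._order)[raw]


@dataclass
class DetectedEvent:
    """One detected binding event, half-open sample interval [start, end)."""

    start_sample: int
    end_sample: int
    t_on: float  # s

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("event must have end > start")


def window_transform(trace: Trace, width: int = 100, step: int = 25) -> WindowFeatures:
    """Compute running means/variances over the record.

    Windows start at samples 0, step, 2*step, ...; a trailing partial
    window is dropped.  Variance uses the unbiased (n-1) denominator.
    """
    x = trace.positions
    if width > x.size:
        raise ValueError(f"trace length {x.size} shorter than window {width}")
    if not (1 <= step <= width):
        raise ValueError("step must satisfy 1 <= step <= width")
    n_win = (x.size - width) // step + 1
    starts = np.arange(n_win) * step
    # O(n) via cumulative sums; stable because positions are O(100) nm
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[starts + width] - c1[starts]
    s2 = c2[starts + width] - c2[starts]
    means = s1 / width
    variances = np.maximum((s2 - s1 * s1 / width) / (width - 1), 0.0)
    return WindowFeatures(starts, means, variances, width, step)


def fit_hmm(features: WindowFeatures, seed: int = 0, *, n_iter: int = 500,
            tol: float = 1e-6, min_separation: float = 3.0) -> HmmModel:
    """Fit the two-state Gaussian HMM to the window features by Baum-Welch.

    States are relabeled so state 0 is unbound (larger log-variance
    emission mean).  If the two fitted states are separated by less than
    ``min_separation`` pooled standard deviations in log-variance the
    data are treated as single-regime: a warning is raised and decoding
    returns all-unbound.  The threshold sits above the ~2.7-SD gap that a
    chance split of a single Gaussian produces (halving a normal at its
    mean leaves two clusters 1.6*sigma apart with within-SD 0.6*sigma),
    while genuinely bound/unbound regimes separate by far more.
    """
    X = features.matrix()
    if X.shape[0] < 20:
        raise ValueError("need at least 20 windows to fit the HMM")
    model = GaussianHMM(n_components=2, covariance_type="diag",
                        n_iter=n_iter, tol=tol,
                        random_state=np.random.default_rng(seed).integers(2**31),
                        min_covar=1e-6, init_params="")
    # Baum-Welch start point: 1-D 2-means on the log-variance feature, so
    # the two states begin as broad (unbound) vs quiet (bound) windows.
    lv = X[:, 1]
    centers = np.percentile(lv, [10.0, 90.0])
    for _ in range(50):
        labels = np.abs(lv[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([lv[labels == j].mean() if np.any(labels == j)
                        else centers[j] for j in (0, 1)])
        if np.allclose(new, centers):
            break
        centers = new
    means, covars = [], []
    for j in (0, 1):
        sel = X[labels == j] if np.any(labels == j) else X
        means.append(sel.mean(axis=0))
        covars.append(np.maximum(sel.var(axis=0), 1e-6))
    model.means_ = np.array(means)
    model.covars_ = np.array(covars)
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    hmm_log = logging.getLogger("hmmlearn.base")
    old_level = hmm_log.level
    hmm_log.setLevel(logging.ERROR)  # millicore log-lik wobble is not actionable
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X)
    finally:
        hmm_log.setLevel(old_level)
    loglik = float(model.score(X))
    if not model.monitor_.converged and len(model.monitor_.history) >= 2 \
            and model.monitor_.history[-1] < model.monitor_.history[-2]:
        raise RuntimeError(f"Baum-Welch failed to improve; last log-likelihood {loglik}")
    logvar_means = model.means_[:, 1]
    order = np.argsort(-logvar_means)        # state 0 := larger logvar (unbound)
    inv = np.empty(2, dtype=int)
    inv[order] = np.arange(2)
    covars = np.array([np.diag(c) for c in model.covars_])
    # compare against the tighter state's spread: the bound state's
    # log-variance is intrinsically broad (head count varies within events)
    sep = abs(logvar_means[0] - logvar_means[1]) / np.sqrt(covars[:, 1].min())
    degenerate = bool(sep < min_separation)
    if degenerate:
        warnings.warn("single-regime data: bound/unbound states not separated; "
                      "decoding all-unbound", RuntimeWarning)
    return HmmModel(
        means=model.means_[order],
        variances=covars[order],
        transmat=model.transmat_[order][:, order],
        startprob=model.startprob_[order],
        log_likelihood=loglik,
        degenerate=degenerate,
        _hmm=model,
        _order=inv,
    )


def decode_events(features: WindowFeatures, model: HmmModel, trace: Trace,
                  min_event_windows: int = 1) -> list[DetectedEvent]:
    """Viterbi-decode windows and map bound runs to coarse sample bounds.

    A maximal run of bound windows [i, j] becomes the coarse event
    [starts[i], starts[j] + width), clipped to the record; runs shorter
    than ``min_event_windows`` are discarded.
    """
    states = model.predict(features)
    bound = np.flatnonzero(states == 1)
    events: list[DetectedEvent] = []
    if bound.size == 0:
        return events
    run_breaks = np.flatnonzero(np.diff(bound) > 1)
    run_starts = np.concatenate([[0], run_breaks + 1])
    run_ends = np.concatenate([run_breaks, [bound.size - 1]])
    n = trace.n_samples
    for i0, i1 in zip(run_starts, run_ends):
        if i1 - i0 + 1 < min_event_windows:
            logger.debug("discarding decoded run of %d windows", i1 - i0 + 1)
            continue
        lo = int(features.starts[bound[i0]])
        hi = min(int(features.starts[bound[i1]]) + features.width, n)
        if hi > lo:
            events.append(DetectedEvent(lo, hi, (hi - lo) / trace.sample_rate_hz))
    return events


def _two_segment_split(x: np.ndarray, min_seg: int = 5) -> int:
    """Sample index maximizing the two-segment Gaussian log-likelihood.

    Each segment gets its own mean and (MLE) variance; ties break to the
    earliest split.  Returns the first index of the right segment.
    """
    n = x.size
    if n < 2 * min_seg:
        raise ValueError("segment too short to split")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    t = np.arange(min_seg, n - min_seg + 1)
    n1 = t.astype(float)
    n2 = n - n1
    v1 = np.maximum(c2[t] / n1 - (c1[t] / n1) ** 2, 1e-12)
    v2 = np.maximum((c2[n] - c2[t]) / n2 - ((c1[n] - c1[t]) / n2) ** 2, 1e-12)
    ll = -0.5 * (n1 * np.log(v1) + n2 * np.log(v2))
    return int(t[np.argmax(ll)])


def _windowed_split(x: np.ndarray, cp_window: int = 50) -> int:
    """Changepoint via a running two-sided window statistic.

    For every candidate point the gain of splitting the surrounding
    ``2*cp_window`` samples into two mean/variance segments over leaving
    them whole (a Gaussian likelihood-ratio statistic on the running
    windows) is evaluated; the best-scoring point is returned.
    """
    n = x.size
    if n < 2 * cp_window:
        return _two_segment_split(x)
    best, best_score = cp_window, -np.inf
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_ll(lo, hi):
        m = hi - lo
        v = max((c2[hi] - c2[lo]) / m - ((c1[hi] - c1[lo]) / m) ** 2, 1e-12)
        return -0.5 * m * np.log(v)

    for t in range(cp_window, n - cp_window + 1):
        score = (seg_ll(t - cp_window, t) + seg_ll(t, t + cp_window)
                 - seg_ll(t - cp_window, t + cp_window))
        if score > best_score:
            best_score, best = score, t
    return best


def refine_changepoints(trace: Trace, event: DetectedEvent, width: int = 100,
                        cp_window: int = 50, method: str = "exact") -> DetectedEvent:
    """Re-estimate event boundaries by changepoint analysis.

    Each coarse boundary is re-located within a neighborhood of two
    window widths on either side (clipped to the record and, for interior
    boundaries, to the event itself remaining non-empty).  ``method``
    "exact" maximizes the two-segment Gaussian likelihood over the whole
    neighborhood; "window" uses the running ``cp_window``-sample variant.
    """
    if method not in ("exact", "window"):
        raise ValueError("method must be 'exact' or 'window'")
    x = trace.positions
    n = x.size
    half = 2 * width

    def refine(bound: int) -> int:
        lo = max(0, bound - half)
        hi = min(n, bound + half)
        if bound - lo < 10 or hi - bound < 10:
            logger.warning("changepoint neighborhood too small at sample %d; "
                           "keeping coarse bound", bound)
            return bound
        seg = x[lo:hi]
        split = (_two_segment_split(seg) if method == "exact"
                 else _windowed_split(seg, cp_window))
        return lo + split

    start = refine(event.start_sample)
    end = refine(event.end_sample)
    if end <= start:
        logger.warning("refinement inverted event at [%d, %d); keeping coarse "
                       "bounds", event.start_sample, event.end_sample)
        return event
    return DetectedEvent(start, end, (end - start) / trace.sample_rate_hz)


def detect_events(trace: Trace, width: int = 100, step: int = 25,
                  cp_window: int = 50, min_event_windows: int = 1,
                  seed: int = 0, refine: bool = True,
                  method: str = "exact") -> list[DetectedEvent]:
    """Full detection pipeline: features -> HMM -> decode -> refine."""
    features = window_transform(trace, width, step)
    model = fit_hmm(features, seed=seed)
    coarse = decode_events(features, model, trace, min_event_windows)
    if not refine:
        return coarse
    refined = [refine_changepoints(trace, ev, width, cp_window, method)
               for ev in coarse]
    # refinement must preserve ordering/non-overlap; clip rare overlaps
    out: list[DetectedEvent] = []
    for ev in refined:
        if out and ev.start_sample < out[-1].end_sample:
            start = out[-1].end_sample
            if ev.end_sample <= start:
                continue
            ev = DetectedEvent(start, ev.end_sample,
                               (ev.end_sample - start) / trace.sample_rate_hz)
        out.append(ev)
    return out


def match_events(detected, truth_events, min_overlap_frac: float = 0.0):
    """Match detected to truth events by interval overlap.

    A pair matches when their overlap exceeds ``min_overlap_frac`` of the
    shorter interval (any positive overlap by default).  Returns
    ``(pairs, recall, precision)`` where pairs is a list of
    ``(truth_index, detected_index)``.
    """
    pairs = []
    used_det: set[int] = set()
    for i, te in enumerate(truth_events):
        best_j, best_ov = None, 0.0
        for j, de in enumerate(detected):
            if j in used_det:
                continue
            ov = (min(te.end_sample, de.end_sample)
                  - max(te.start_sample, de.start_sample))
            shorter = min(te.end_sample - te.start_sample,
                          de.end_sample - de.start_sample)
            if ov > best_ov and ov > min_overlap_frac * shorter:
                best_j, best_ov = j, ov
        if best_j is not None:
            pairs.append((i, best_j))
            used_det.add(best_j)
    n_truth = len(truth_events)
    n_det = len(detected)
    recall = len(pairs) / n_truth if n_truth else 1.0
    precision = len(pairs) / n_det if n_det else 1.0
    return pairs, recall, precision
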