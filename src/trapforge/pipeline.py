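"""End-to-end pipeline orchestration with reproducible configuration.

A run config (YAML/dict) lists the stages to execute and their
parameters.  Stages: ``simulate`` (one synthetic record per condition),
``detect`` (HMM + changepoint events per record), ``features``
(per-event metrics and condition summaries), ``table1`` (derived
head-count table) and ``fit_bell`` (one Bell fit per construct/Pi
group).  Any suffix of the chain can run on externally provided inputs.

Reproducibility: one global seed; every stage/condition derives its own
child seed through ``numpy.random.SeedSequence(spawn_key=(seed, index))``
so stages can be rerun independently; the seed and parameters are
recorded in the manifest together with a sha256 for every artifact.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .bell import BellPoint, fit_bell
from .calibration import equipartition_stiffness
from .config import SimConfig
from .detect import detect_events
from .ensemble_table import build_table, write_table
from .features import event_metrics, summarize_condition
from .simulate import simulate_ensemble_trace

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "features", "table1", "fit_bell")

_SCHEMA_KEYS = {
    "seed", "out_dir", "stages", "conditions", "sim_overrides",
    "detect", "features", "table1", "fit_bell", "inputs",
}
_CONDITION_KEYS = {"label", "construct", "pi_mM", "k_trap", "duration_s",
                   "overrides"}


def stage_seed(seed: int, index: int) -> int:
    """Deterministic per-stage/condition child seed (documented scheme)."""
    return int(np.random.SeedSequence(entropy=seed,
                                      spawn_key=(index,)).generate_state(1)[0]
               % (2 ** 31))


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, data: dict):
        unknown = set(data) - _SCHEMA_KEYS
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("run config requires an explicit seed")
        self.seed = int(data["seed"])
        self.out_dir = Path(data.get("out_dir", "trapforge_run"))
        self.stages = list(data.get("stages", STAGES))
        for st in self.stages:
            if st not in STAGES:
                raise ValueError(f"unknown stage {st!r}; valid: {STAGES}")
        self.conditions = data.get("conditions", [])
        for cond in self.conditions:
            bad = set(cond) - _CONDITION_KEYS
            if bad:
                raise ValueError(f"unknown condition keys: {sorted(bad)}")
        self.sim_overrides = data.get("sim_overrides", {})
        self.detect = data.get("detect", {})
        self.features = data.get("features", {})
        self.table1 = data.get("table1", {})
        self.fit_bell = data.get("fit_bell", {})
        self.inputs = data.get("inputs", [])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    cond_meta = []

    trace_paths: list[tuple[dict, Path]] = []
    if "simulate" in config.stages:
        if not config.conditions:
            raise ValueError("simulate stage requires a conditions list")
        for i, cond in enumerate(config.conditions):
            label = cond.get("label",
                             f"{cond.get('construct', 'sim')}_pi{cond.get('pi_mM', 0)}"
                             f"_k{cond['k_trap']}")
            overrides = dict(config.sim_overrides)
            overrides.update(cond.get("overrides", {}))
            sim = SimConfig(k_trap=float(cond["k_trap"]),
                            duration_s=float(cond.get("duration_s", 20.0)),
                            seed=stage_seed(config.seed, i),
                            pi_mM=float(cond.get("pi_mM", 0.0)),
                            **overrides)
            trace, truth = simulate_ensemble_trace(sim)
            trace.condition = label
            tpath = out / f"{label}.csv"
            tio.write_trace(tpath, trace)
            tio.write_truth(out / f"{label}_truth.tsv", truth)
            artifacts += [tpath, out / f"{label}_truth.tsv",
                          out / f"{label}_truth_transitions.tsv"]
            trace_paths.append((cond, tpath))
            cond_meta.append({"label": label, **{k: cond.get(k) for k in
                                                 ("construct", "pi_mM", "k_trap")},
                              "sim_seed": sim.seed})
            logger.info("simulated %s: %d truth events", label, truth.n_events)
    else:
        for i, p in enumerate(config.inputs):
            trace_paths.append(({"label": Path(p).stem}, Path(p)))

    events_by_label: dict[str, list] = {}
    if "detect" in config.stages:
        for j, (cond, tpath) in enumerate(trace_paths):
            trace = tio.read_trace(tpath)
            label = trace.condition or tpath.stem
            evs = detect_events(
                trace,
                width=int(config.detect.get("window", 100)),
                step=int(config.detect.get("window_step", 25)),
                cp_window=int(config.detect.get("cp_window", 50)),
                min_event_windows=int(config.detect.get("min_event_windows", 1)),
                method=config.detect.get("method", "exact"),
                seed=stage_seed(config.seed, 1000 + j),
            )
            epath = out / f"{label}_events.tsv"
            tio.write_events(epath, evs, trace.sample_rate_hz)
            artifacts.append(epath)
            events_by_label[label] = evs
            logger.info("detected %d events in %s", len(evs), label)

    all_metrics = None
    summaries = None
    if "features" in config.stages:
        frames = []
        for cond, tpath in trace_paths:
            trace = tio.read_trace(tpath)
            label = trace.condition or tpath.stem
            if label in events_by_label:
                evs = events_by_label[label]
            else:
                from .detect import DetectedEvent
                df = tio.read_events(out / f"{label}_events.tsv")
                evs = [DetectedEvent(int(r.start_sample), int(r.end_sample),
                                     float(r.t_on_s))
                       for r in df.itertuples()]
            k_trap = None
            if config.features.get("use_calibration"):
                k_trap = equipartition_stiffness(trace).k_trap_hat
            m = event_metrics(trace, evs,
                              window_ms=float(config.features.get("window_ms", 5.0)),
                              k_trap=k_trap, condition=label)
            for key in ("construct", "pi_mM"):
                if key in cond:
                    m[key] = cond[key]
            frames.append(m)
        non_empty = [f for f in frames if len(f)]
        all_metrics = pd.concat(non_empty or frames, ignore_index=True)
        mpath = out / "event_metrics.tsv"
        all_metrics.to_csv(mpath, sep="\t", index=False, float_format="%.17g")
        group = [c for c in ("construct", "pi_mM", "k_trap")
                 if c in all_metrics.columns]
        summaries = summarize_condition(all_metrics, group or ["condition"])
        spath = out / "condition_summaries.tsv"
        summaries.to_csv(spath, sep="\t", index=False, float_format="%.17g")
        artifacts += [mpath, spath]

    if "table1" in config.stages:
        if summaries is None:
            raise ValueError("table1 stage needs the features stage output")
        table = build_table(summaries,
                            step_nm=float(config.table1.get("step_nm", 7.0)),
                            force_col="peak_force_mean")
        tpath = out / "ensemble_table.tsv"
        write_table(tpath, table)
        artifacts.append(tpath)

    fits = {}
    if "fit_bell" in config.stages:
        if summaries is None:
            raise ValueError("fit_bell stage needs condition summaries")
        by = [c for c in ("construct", "pi_mM") if c in summaries.columns]
        groups = summaries.groupby(by) if by else [("all", summaries)]
        for key, g in groups:
            if len(g) < 3:
                logger.warning("skipping Bell fit for %s: %d points", key, len(g))
                continue
            pts = [BellPoint(r.peak_force_mean, r.k_det, r.k_det_sem,
                             int(r.n_events)) for r in g.itertuples()]
            fit = fit_bell(pts, weighted=bool(config.fit_bell.get("weighted", True)))
            name = "_".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
            fits[name] = fit.to_dict()
        fpath = out / "bell_fits.json"
        with open(fpath, "w") as fh:
            json.dump(fits, fh, indent=2)
        artifacts.append(fpath)

    manifest = {
        "seed": config.seed,
        "stages": config.stages,
        "conditions": cond_meta,
        "files": {str(p.relative_to(out)): _sha256(p)
                  for p in artifacts if p.exists()},
        "bell_fits": fits,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
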