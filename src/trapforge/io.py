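"""Plain-text readers/writers for traces, truth annotations and event tables.

Trace file format: a CSV whose header comment lines carry the metadata,

    # k_trap_pN_per_nm=0.04
    # sample_rate_hz=5000.0
    # temperature_K=298.15
    # condition=WT 0 mM Pi
    position_nm
    -3.1415
    ...

Time is implicit (uniform sampling).  Ground truth is stored alongside as
two TSVs: an event table (event_id, start_sample, end_sample) and a
transitions table (event_id, time_s, kind, n_attached_after, mean_nm).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trace import GroundTruth, Trace, TrueEvent


class TraceFormatError(ValueError):
    """Raised when a trace file is malformed."""


_REQUIRED = {
    "k_trap_pN_per_nm": "k_trap",
    "sample_rate_hz": "sample_rate_hz",
    "temperature_K": "temperature_K",
}


def write_trace(path, trace: Trace) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# k_trap_pN_per_nm={trace.k_trap!r}\n")
        fh.write(f"# sample_rate_hz={trace.sample_rate_hz!r}\n")
        fh.write(f"# temperature_K={trace.temperature_K!r}\n")
        fh.write(f"# condition={trace.condition}\n")
        fh.write("position_nm\n")
        np.savetxt(fh, trace.positions, fmt="%.17g")


def read_trace(path) -> Trace:
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                header_lines += 1
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceFormatError(
                        f"{path}: malformed header at line {lineno}: {line!r}")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            else:
                if line.strip() != "position_nm":
                    raise TraceFormatError(
                        f"{path}: expected 'position_nm' column header at line "
                        f"{lineno}, got {line!r}")
                break
        else:
            raise TraceFormatError(f"{path}: no data section found")
    for key in _REQUIRED:
        if key not in meta:
            raise TraceFormatError(f"{path}: missing required header '{key}'")
    positions = np.loadtxt(path, skiprows=header_lines + 1, ndmin=1)
    return Trace(
        positions=positions,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        k_trap=float(meta["k_trap_pN_per_nm"]),
        temperature_K=float(meta["temperature_K"]),
        condition=meta.get("condition", ""),
    )


def write_truth(path, truth: GroundTruth) -> None:
    """Write the event table; transitions go to `<path stem>_transitions.tsv`."""
    path = Path(path)
    ev = pd.DataFrame(
        [(i, e.start_sample, e.end_sample) for i, e in enumerate(truth.events)],
        columns=["event_id", "start_sample", "end_sample"],
    )
    ev.to_csv(path, sep="\t", index=False)
    rows = []
    for i, e in enumerate(truth.events):
        for (t, kind, n_after, mean_nm) in e.transitions:
            rows.append((i, t, kind, n_after, mean_nm))
    tr = pd.DataFrame(rows, columns=["event_id", "time_s", "kind",
                                     "n_attached_after", "mean_nm"])
    tr.to_csv(path.with_name(path.stem + "_transitions.tsv"), sep="\t",
              index=False, float_format="%.17g")


def read_truth(path) -> GroundTruth:
    path = Path(path)
    ev = pd.read_csv(path, sep="\t")
    trans_path = path.with_name(path.stem + "_transitions.tsv")
    trans = pd.read_csv(trans_path, sep="\t") if trans_path.exists() else None
    events = []
    for _, row in ev.iterrows():
        transitions = []
        if trans is not None:
            sub = trans[trans.event_id == row.event_id]
            transitions = list(sub[["time_s", "kind", "n_attached_after",
                                    "mean_nm"]].itertuples(index=False, name=None))
        events.append(TrueEvent(int(row.start_sample), int(row.end_sample),
                                transitions))
    return GroundTruth(events)


def write_events(path, events, sample_rate_hz: float) -> None:
    """Write detected events as TSV: event_id, start_sample, end_sample, t_on_s."""
    df = pd.DataFrame(
        [(i, e.start_sample, e.end_sample,
          (e.end_sample - e.start_sample) / sample_rate_hz)
         for i, e in enumerate(events)],
        columns=["event_id", "start_sample", "end_sample", "t_on_s"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
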