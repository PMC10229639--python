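"""Head counts and per-head forces from ensemble displacements.

Assuming each myosin head contributes one 7 nm powerstroke and that at
the peak every attached head bears a resistive load, a mean peak
displacement converts to a head count (displacement / 7 nm), an ensemble
force (k_trap * displacement) and a force per head (force / heads, which
algebraically equals k_trap * 7 nm whenever both derived columns come
from the same displacement).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import logging

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STEP_NM = 7.0


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (0.705 -> 0.71)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures (half-up)."""
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = sig - 1 - d.adjusted()
    q = Decimal(1).scaleb(-shift)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def heads_from_displacement(displacement: float,
                            step_nm: float = DEFAULT_STEP_NM) -> float:
    """Average number of heads driving a displacement: displacement / step."""
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    return displacement / step_nm


def force_from_displacement(displacement: float, k_trap: float) -> float:
    """Ensemble force k_trap * displacement (pN)."""
    if k_trap <= 0:
        raise ValueError("k_trap must be positive")
    return k_trap * displacement


@dataclass
class EnsembleRow:
    construct: str
    pi_mM: float
    k_trap: float
    displacement: float       # nm, mean peak displacement
    force: float              # pN
    heads: float              # raw displacement/step
    force_per_head: float     # pN
    step_nm: float = DEFAULT_STEP_NM

    def display(self) -> dict:
        """Row at the printed precisions: heads 1 dp, forces 3 sig figs."""
        d = asdict(self)
        d["heads"] = round_half_up(self.heads, 1)
        d["force"] = round_sig(self.force, 3)
        d["force_per_head"] = round_sig(self.force_per_head, 3)
        d["displacement"] = round_half_up(self.displacement, 1)
        return d


def build_table(summaries: pd.DataFrame, step_nm: float = DEFAULT_STEP_NM,
                force_col: str | None = None) -> pd.DataFrame:
    """Assemble the derived-columns table from condition summaries.

    ``summaries`` needs columns construct, pi_mM, k_trap and
    peak_displacement_mean; when ``force_col`` names a column holding the
    mean of per-event forces it is used as the force (that is how the
    original tabulation averaged), otherwise force = k_trap x mean
    displacement.  Heads = displacement/step and force_per_head =
    force/heads are always derived.  Full precision is kept; use
    ``EnsembleRow.display`` or the *_disp columns for printing.
    """
    rows = []
    for _, s in summaries.iterrows():
        if "k_trap" not in s or pd.isna(s["k_trap"]):
            logger.warning("summary row without k_trap skipped: %s", dict(s))
            continue
        disp = float(s["peak_displacement_mean"])
        if force_col is not None and force_col in s and not pd.isna(s[force_col]):
            force = float(s[force_col])
            logger.debug("row %s: per-event mean force", s.get("construct"))
        else:
            force = force_from_displacement(disp, float(s["k_trap"]))
        heads = heads_from_displacement(disp, step_nm)
        row = EnsembleRow(
            construct=str(s.get("construct", "")),
            pi_mM=float(s.get("pi_mM", 0.0)),
            k_trap=float(s["k_trap"]),
            displacement=disp,
            force=force,
            heads=heads,
            force_per_head=force / heads if heads > 0 else 0.0,
            step_nm=step_nm,
        )
        d = asdict(row)
        disp_cols = row.display()
        d.update({f"{k}_disp": disp_cols[k]
                  for k in ("displacement", "force", "heads", "force_per_head")})
        rows.append(d)
    return pd.DataFrame(rows)


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
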