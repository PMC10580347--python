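"""Drug-likeness filters: Lipinski rule of five, PAINS flag bookkeeping.

Descriptors (molecular weight, LogP, H-bond donor/acceptor counts) are
inputs, not computed from structure; a PAINS pass/fail flag supplied by an
external substructure screen is carried through unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = ["CompoundDescriptors", "lipinski_ro5", "ro5_table"]


@dataclass
class CompoundDescriptors:
    """Physicochemical descriptors of one compound."""

    compound_id: str
    mw: float        # daltons
    logp: float
    hbd: int         # H-bond donors
    hba: int         # H-bond acceptors
    pains_flag: Optional[bool] = None  # True = PAINS alert (externally supplied)

    def __post_init__(self) -> None:
        if self.mw is None or not math.isfinite(self.mw) or self.mw <= 0:
            raise ValueError(f"{self.compound_id}: mw must be positive and finite")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError(f"{self.compound_id}: hbd/hba must be non-negative")


def lipinski_ro5(d: CompoundDescriptors) -> tuple[int, bool]:
    """Count rule-of-five violations and decide drug-likeness.

    Violations: MW > 500 Da, LogP > 5, H-bond donors > 5, acceptors > 10.
    The compound passes with at most one violation (standard usage).
    """
    for name in ("mw", "logp", "hbd", "hba"):
        value = getattr(d, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"{d.compound_id}: missing descriptor {name!r}")
    violations = int(d.mw > 500) + int(d.logp > 5) + int(d.hbd > 5) + int(d.hba > 10)
    return violations, violations <= 1


def ro5_table(table: Union[pd.DataFrame, str, Path]) -> pd.DataFrame:
    """Evaluate RO5 for a descriptor table.

    Columns ``compound_id, mw, logp, hbd, hba`` with optional ``pains``;
    output adds ``ro5_violations`` and ``ro5_pass``.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    out = table.copy()
    v_list, p_list = [], []
    for _, row in out.iterrows():
        d = CompoundDescriptors(
            str(row["compound_id"]), float(row["mw"]), float(row["logp"]),
            int(row["hbd"]), int(row["hba"]),
            bool(row["pains"]) if "pains" in out.columns and pd.notna(row.get("pains")) else None,
        )
        v, p = lipinski_ro5(d)
        v_list.append(v)
        p_list.append(p)
    out["ro5_violations"] = v_list
    out["ro5_pass"] = p_list
    return out
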