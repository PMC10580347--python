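"""MM-PBSA-style binding free-energy aggregation and strength classification.

The binding free energy of a complex is the sum of four end-state
components, each in kcal/mol:

    dG_bind = dE_vdw + dE_ele + dG_pol + dG_np

(van der Waals, electrostatic, polar solvation, nonpolar solvation).  The
components themselves come from upstream tools; this module only aggregates
them — either from one time-averaged row per complex, or from per-frame
component tables averaged over the trailing convergence window.

Classification uses the conventional affinity bands (kcal/mol):
Weak −1.36 to −5.46, Medium −6.83 to −8.19, Strong −9.56 to −12.29,
Very strong −13.66 to −16.39.  The bands are gapped and bounded, so values
falling between bands or beyond the strongest one are assigned the label of
the nearest band boundary with an "(extrapolated)" qualifier, and values
weaker than −1.36 are "negligible".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "COMPONENT_FIELDS",
    "STRENGTH_BANDS",
    "EnergyComponents",
    "aggregate",
    "classify_strength",
    "aggregate_table",
    "aggregate_frame_table",
]

COMPONENT_FIELDS = ("e_vdw", "e_ele", "g_pol", "g_np")

#: (label, weak boundary, strong boundary) in kcal/mol, weakest band first
STRENGTH_BANDS = (
    ("Weak", -1.36, -5.46),
    ("Medium", -6.83, -8.19),
    ("Strong", -9.56, -12.29),
    ("Very strong", -13.66, -16.39),
)


@dataclass
class EnergyComponents:
    """Energy decomposition of one protein–ligand complex (kcal/mol)."""

    complex_id: str
    e_vdw: float
    e_ele: float
    g_pol: float
    g_np: float

    @property
    def g_bind(self) -> float:
        return aggregate(self)


def aggregate(components: EnergyComponents) -> float:
    """Sum the four energy components into the binding free energy.

    Full precision is retained; round to 2 decimals only for display.
    Raises ``ValueError`` naming any missing or non-finite component.
    """
    total = 0.0
    for name in COMPONENT_FIELDS:
        value = getattr(components, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"{components.complex_id}: missing energy component {name!r}")
        if not math.isfinite(value):
            raise ValueError(f"{components.complex_id}: non-finite energy component {name!r}")
        total += float(value)
    return total


def classify_strength(g_bind: float) -> str:
    """Map a binding free energy (kcal/mol) onto an affinity label.

    Values inside a band get its label; values weaker than the weakest band
    boundary are "negligible"; values in a gap between bands or beyond the
    strongest band take the nearest boundary's label, qualified with
    "(extrapolated)".  More negative energies never map to a weaker label.
    """
    if not math.isfinite(g_bind):
        raise ValueError("g_bind must be finite")
    weakest = STRENGTH_BANDS[0][1]
    if g_bind > weakest:
        return "negligible"
    for label, weak, strong in STRENGTH_BANDS:
        if strong <= g_bind <= weak:
            return label
    # in a gap between bands or beyond the strongest band
    best_label, best_dist = None, math.inf
    for label, weak, strong in STRENGTH_BANDS:
        for bound in (weak, strong):
            d = abs(g_bind - bound)
            if d < best_dist:
                best_label, best_dist = label, d
    return f"{best_label} (extrapolated)"


def aggregate_table(table: Union[pd.DataFrame, str, Path]) -> pd.DataFrame:
    """Aggregate a per-complex component table.

    Input columns: ``complex_id, e_vdw, e_ele, g_pol, g_np`` (TSV path or
    DataFrame); output adds ``g_bind`` and ``strength``.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    missing = [c for c in ("complex_id", *COMPONENT_FIELDS) if c not in table.columns]
    if missing:
        raise ValueError(f"component table missing column(s): {missing}")
    out = table.copy()
    g_bind = []
    for _, row in out.iterrows():
        comps = EnergyComponents(str(row["complex_id"]),
                                 *(float(row[c]) for c in COMPONENT_FIELDS))
        g_bind.append(aggregate(comps))
    out["g_bind"] = g_bind
    out["strength"] = [classify_strength(g) for g in g_bind]
    return out


def aggregate_frame_table(
    table: Union[pd.DataFrame, str, Path],
    fraction: float = 0.2,
) -> pd.DataFrame:
    """Aggregate per-frame component rows over the trailing window.

    Input columns: ``complex_id, frame, e_vdw, e_ele, g_pol, g_np`` with one
    row per frame per complex.  For each complex the final
    ``ceil(fraction * n_frames)`` frames (by ``frame`` order) are averaged
    componentwise, then aggregated as usual.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    rows = []
    for cid, sub in table.groupby("complex_id", sort=True):
        sub = sub.sort_values("frame")
        n_keep = math.ceil(fraction * len(sub))
        tail = sub.iloc[len(sub) - n_keep:]
        rows.append({"complex_id": cid,
                     **{c: float(tail[c].mean()) for c in COMPONENT_FIELDS}})
    return aggregate_table(pd.DataFrame(rows))
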