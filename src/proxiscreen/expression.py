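"""Two-group differential-expression screen.

Per gene: a two-sided Welch t-test between case and control samples plus a
pooled-SD Cohen's d effect size.  A gene is selected when p < alpha
(default 0.05) and |d| > d_min (default 0.8); no multiple-testing
correction is applied by default (an optional Benjamini–Hochberg FDR column
can be requested, but selection still uses the raw thresholds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneTestResult",
    "cohens_d",
    "gene_test",
    "screen_expression",
    "load_expression",
]

ALPHA_DEFAULT = 0.05
D_MIN_DEFAULT = 0.8


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with two-group sample labels.

    ``values``: DataFrame indexed by gene, columns are sample ids (log-scale
    expression).  ``groups``: Series mapping sample id -> "case"/"control".
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")
        for g in ("case", "control"):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"need at least 2 '{g}' samples")

    @property
    def case(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups == "case"]

    @property
    def control(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups == "control"]


@dataclass
class GeneTestResult:
    gene: str
    mean_case: float
    mean_control: float
    cohens_d: float
    p_value: float
    selected: bool


def cohens_d(case: np.ndarray, control: np.ndarray) -> float | None:
    """Pooled-SD standardized mean difference (case minus control).

    d = (mean1 - mean2) / s_pooled with
    s_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).
    Returns ``None`` (undefined) when the pooled SD is zero.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = case.size, control.size
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d needs at least 2 values per group")
    s1, s2 = case.var(ddof=1), control.var(ddof=1)
    pooled = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0.0:
        return None
    return float((case.mean() - control.mean()) / pooled)


def gene_test(
    case: np.ndarray,
    control: np.ndarray,
    gene: str = "",
    alpha: float = ALPHA_DEFAULT,
    d_min: float = D_MIN_DEFAULT,
) -> GeneTestResult | None:
    """Welch t-test + effect size for one gene; ``None`` if d is undefined."""
    d = cohens_d(case, control)
    if d is None:
        logger.warning("gene %s: zero pooled SD, excluded", gene or "<unnamed>")
        return None
    p = float(stats.ttest_ind(case, control, equal_var=False).pvalue)
    return GeneTestResult(
        gene=gene,
        mean_case=float(np.mean(case)),
        mean_control=float(np.mean(control)),
        cohens_d=d,
        p_value=p,
        selected=bool(p < alpha and abs(d) > d_min),
    )


def screen_expression(
    mat: ExpressionMatrix,
    alpha: float = ALPHA_DEFAULT,
    d_min: float = D_MIN_DEFAULT,
    fdr: bool = False,
) -> pd.DataFrame:
    """Test every gene; vectorized over the whole matrix.

    Returns a DataFrame with one row per testable gene (zero-pooled-SD genes
    are excluded with a warning): ``gene, mean_case, mean_control, cohens_d,
    p_value, selected`` plus ``q_value`` when ``fdr=True`` (informational
    only; selection always uses the raw p/d thresholds).
    """
    case = mat.case.to_numpy(dtype=float)
    control = mat.control.to_numpy(dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    s1 = case.var(axis=1, ddof=1)
    s2 = control.var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    testable = pooled > 0
    if (~testable).any():
        logger.warning("%d gene(s) with zero pooled SD excluded: %s",
                       (~testable).sum(), list(mat.values.index[~testable])[:10])
    mean_case = case.mean(axis=1)
    mean_control = control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean_case - mean_control) / pooled
    p = stats.ttest_ind(case, control, axis=1, equal_var=False).pvalue
    out = pd.DataFrame(
        {
            "gene": mat.values.index,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "cohens_d": d,
            "p_value": p,
        }
    )[testable]
    out["selected"] = (out["p_value"] < alpha) & (out["cohens_d"].abs() > d_min)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    logger.info("expression screen: %d/%d genes selected (alpha=%g, |d|>%g)",
                int(out["selected"].sum()), len(out), alpha, d_min)
    return out.reset_index(drop=True)


def load_expression(
    matrix_path: Union[str, Path],
    groups_path: Union[str, Path],
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene) and a two-column sample sheet
    (``sample<TAB>group``)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(groups_path, sep="\t", header=None, names=["sample", "group"],
                        dtype=str, comment="#")
    groups = sheet.set_index("sample")["group"]
    return ExpressionMatrix(values=values, groups=groups)
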