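"""Relative qPCR quantification by the comparative CT (2^-ΔΔCT) method.

A plate table holds one cycle-threshold (CT) value per (sample, gene,
dose, replicate). Target-gene CTs are normalised to a same-sample
reference gene (ΔCT, here typically β-actin), converted to relative
expression 2^-ΔCT, aggregated per dose by geometric mean (arithmetic
mean of ΔCT — the natural average for an exponential quantity), and
expressed as fold change versus the untreated control dose. Dose
dependence is tested by regressing log2 relative expression on dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

PLATE_COLUMNS = ["sample_id", "gene", "dose", "replicate", "ct"]
LN2 = math.log(2.0)


@dataclass(frozen=True)
class FoldChange:
    fold: float
    sd: float
    n_treated: int
    n_control: int


def read_plate_tsv(path_or_handle) -> pd.DataFrame:
    df = pd.read_csv(path_or_handle, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    return df


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """Relative expression 2^-(target_ct - reference_ct)."""
    if target_ct <= 0 or reference_ct <= 0:
        raise ValueError("CT values must be positive")
    return 2.0 ** -(target_ct - reference_ct)


def relative_expression(plate: pd.DataFrame, reference: str = "ACTB") -> pd.DataFrame:
    """Per-replicate relative expression of every target gene.

    Each target record is paired with the reference-gene CT of the same
    (sample_id, dose, replicate); a missing reference record is an error.
    Returns columns sample_id, gene, dose, replicate, delta_ct, rel_expr.
    """
    if (pd.to_numeric(plate["ct"], errors="raise") <= 0).any():
        raise ValueError("CT values must be positive")
    ref = plate[plate["gene"] == reference]
    if ref.empty:
        raise InsufficientDataError(f"no records for reference gene {reference!r}")
    key = ["sample_id", "dose", "replicate"]
    ref_ct = ref.set_index(key)["ct"]
    if ref_ct.index.has_duplicates:
        ref_ct = ref_ct.groupby(level=key).mean()
    targets = plate[plate["gene"] != reference].copy()
    matched = targets.set_index(key).index
    missing = [k for k in matched if k not in ref_ct.index]
    if missing:
        raise InsufficientDataError(
            f"target records without a same-sample reference CT: {missing[:3]}"
        )
    targets["delta_ct"] = targets["ct"].to_numpy(float) - ref_ct.loc[matched].to_numpy(
        float
    )
    targets["rel_expr"] = 2.0 ** -targets["delta_ct"]
    return targets[key[:1] + ["gene", "dose", "replicate", "delta_ct", "rel_expr"]]


def fold_change(treated, control) -> FoldChange:
    """Fold change of treated over control relative-expression replicates.

    The point estimate is the ratio of geometric means (equal to
    2^-ΔΔCT for single replicates); the sd follows by first-order
    propagation of the replicate spread of log2 expression.
    """
    t = np.asarray(list(treated), dtype=float)
    c = np.asarray(list(control), dtype=float)
    if t.size == 0 or c.size == 0:
        raise InsufficientDataError("fold_change needs non-empty replicate sets")
    if (t <= 0).any() or (c <= 0).any():
        raise ValueError("relative expression values must be positive")
    lt, lc = np.log2(t), np.log2(c)
    fold = float(2.0 ** (lt.mean() - lc.mean()))
    var_log2 = (lt.var(ddof=1) / t.size if t.size > 1 else 0.0) + (
        lc.var(ddof=1) / c.size if c.size > 1 else 0.0
    )
    sd = float(fold * LN2 * math.sqrt(var_log2))
    return FoldChange(fold=fold, sd=sd, n_treated=int(t.size), n_control=int(c.size))


def dose_trend(doses, rel_exprs) -> tuple[float, float]:
    """Least-squares slope of log2 relative expression on dose, with its
    two-sided p-value. Requires at least 3 distinct doses."""
    d = np.asarray(list(doses), dtype=float)
    y = np.asarray(list(rel_exprs), dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and expression values must align")
    if np.unique(d).size < 3:
        raise InsufficientDataError("dose trend needs >= 3 distinct doses")
    res = stats.linregress(d, np.log2(y))
    return float(res.slope), float(res.pvalue)


def summarize_plate(
    plate: pd.DataFrame, reference: str = "ACTB", control_dose: float = 0.0
) -> pd.DataFrame:
    """Full comparative-CT summary of a plate.

    One row per (gene, dose): replicate count, geometric-mean relative
    expression with propagated sd, fold change versus ``control_dose``
    with propagated sd, and the gene-level dose-trend slope and p-value
    (repeated across the gene's rows; NaN with < 3 distinct doses).
    """
    rel = relative_expression(plate, reference=reference)
    rows = []
    for gene, sub in rel.groupby("gene", sort=True):
        doses = np.sort(sub["dose"].unique())
        if control_dose not in doses:
            raise InsufficientDataError(
                f"gene {gene}: control dose {control_dose} absent from plate"
            )
        control = sub.loc[sub["dose"] == control_dose, "rel_expr"].to_numpy(float)
        try:
            slope, trend_p = dose_trend(sub["dose"], sub["rel_expr"])
        except InsufficientDataError:
            slope, trend_p = float("nan"), float("nan")
        for dose in doses:
            vals = sub.loc[sub["dose"] == dose, "rel_expr"].to_numpy(float)
            logs = np.log2(vals)
            gmean = float(2.0 ** logs.mean())
            gsd = float(gmean * LN2 * logs.std(ddof=1)) if vals.size > 1 else 0.0
            fc = fold_change(vals, control)
            rows.append(
                {
                    "gene": gene,
                    "dose": float(dose),
                    "n": int(vals.size),
                    "relative_expression": gmean,
                    "relative_expression_sd": gsd,
                    "fold_change": fc.fold,
                    "fold_change_sd": fc.sd,
                    "trend_slope": slope,
                    "trend_p": trend_p,
                }
            )
    return pd.DataFrame(rows)
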