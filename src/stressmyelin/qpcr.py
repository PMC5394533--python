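"""ΔΔCt relative quantification with reference-gene normalization.

Replicate Ct values are averaged per sample × gene, normalized to an
endogenous reference gene (GAPDH by default) to give ΔCt, and expressed as
fold change relative to the control-group mean ΔCt: fold = 2^(−ΔΔCt).
Folds are formed per sample so that a dispersion (SEM across samples) can
be reported per gene × group; the control-group mean fold is 1 by
construction. Amplification efficiency is fixed at 2.0 per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RelExpression", "validate_ct_table", "delta_ct", "ddct_fold"]

CT_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]


@dataclass
class RelExpression:
    """Per-sample fold values and the gene × group summary (fold, sem, n)."""

    per_sample: pd.DataFrame  # columns: sample, group, gene, fold
    summary: pd.DataFrame  # columns: gene, group, fold, sem, n


def validate_ct_table(table: pd.DataFrame, reference_gene: str = "Gapdh") -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any() or table["ct"].isna().any():
        raise ValueError("all Ct values must be positive")
    have_ref = set(table.loc[table["gene"] == reference_gene, "sample"])
    lacking = sorted(set(table["sample"]) - have_ref)
    if lacking:
        raise ValueError(f"reference gene {reference_gene!r} missing for samples: {lacking}")
    return table


def delta_ct(table: pd.DataFrame, reference_gene: str = "Gapdh") -> pd.DataFrame:
    """ΔCt per sample × gene: mean target Ct minus mean reference Ct.

    Replicates are averaged on the Ct scale before subtraction. The
    reference gene itself is dropped from the output (its ΔCt is 0).
    """
    table = validate_ct_table(table, reference_gene)
    mean_ct = (
        table.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample")["ct"]
    out = mean_ct[mean_ct["gene"] != reference_gene].copy()
    out["delta_ct"] = out["ct"].to_numpy() - ref.loc[out["sample"]].to_numpy()
    return out.drop(columns="ct")


def ddct_fold(deltas: pd.DataFrame, control_group: str = "HC") -> RelExpression:
    """Fold change relative to the control group via ΔΔCt.

    Per sample: fold = 2^(−(ΔCt_sample − mean ΔCt of control group for that
    gene)). The group-level fold is the geometric mean of per-sample folds —
    the fold scale is multiplicative, and this makes the control-group fold
    exactly 1 by construction; the reported SEM is the dispersion of the
    per-sample folds themselves.
    """
    if control_group not in set(deltas["group"]):
        raise ValueError(f"control group {control_group!r} absent from ΔCt table")
    per = deltas.copy()
    control_mean = (
        per[per["group"] == control_group].groupby("gene")["delta_ct"].mean()
    )
    genes_missing = sorted(set(per["gene"]) - set(control_mean.index))
    if genes_missing:
        raise ValueError(f"control group empty for genes: {genes_missing}")
    per["fold"] = 2.0 ** -(per["delta_ct"].to_numpy() - control_mean.loc[per["gene"]].to_numpy())
    summary = (
        per.groupby(["gene", "group"], sort=False)["fold"]
        .agg(
            fold=lambda v: float(np.exp(np.mean(np.log(v)))),
            sem=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            n="size",
        )
        .reset_index()
    )
    return RelExpression(
        per_sample=per[["sample", "group", "gene", "fold"]], summary=summary
    )
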