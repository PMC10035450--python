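"""Immune cell scores, quartile dichotomization, and the AGI composite.

An immune cell score is the median expression of a cell type's marker genes
in one sample; single-gene scores (PD-L1 = CD274, CD8 = CD8A) pass the gene
value through. Scores are dichotomized Low/High at the cohort's third
quartile (linear-interpolation quantile, strict inequality: a value exactly
at Q3 is Low, so an all-constant cohort is everyone-Low).

AGI ("any genomic instability") is the OR of the TP53 and HRD calls:
Mut-like or HRD+ in either slot gives AGI regardless of the other; WT-like
and HRD- gives NGI; any remaining combination with a missing call is
indeterminate, because the missing slot could still have made the tumor AGI.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import DataError, ExpressionMatrix, MarkerPanel

logger = logging.getLogger("gipipe")

MUT_LIKE, WT_LIKE = "Mut-like", "WT-like"
HRD_POS, HRD_NEG = "HRD+", "HRD-"
AGI, NGI, INDETERMINATE = "AGI", "NGI", "indeterminate"
MISSING = "missing"


def compute_scores(
    expr: ExpressionMatrix,
    panel: MarkerPanel,
    *,
    min_gene_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-sample score table (samples x score names).

    Missing genes are dropped per sample; a score with fewer than
    ``min_gene_fraction`` of its panel genes observed in a sample is missing
    for that sample. A panel with no gene at all in the matrix is an error.
    """
    gene_set = set(expr.gene_ids)
    out = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    for score, genes in panel.cell_type_to_genes.items():
        present = [g for g in genes if g in gene_set]
        if not present:
            raise DataError(
                f"panel {panel.name!r}, score {score!r}: none of its "
                f"{len(genes)} genes are in the expression matrix"
            )
        block = expr.df.loc[present]
        observed_frac = block.notna().sum(axis=0) / len(genes)
        medians = block.median(axis=0, skipna=True)
        medians[observed_frac < min_gene_fraction] = np.nan
        out[score] = medians
    for score, gene in panel.single_gene_scores.items():
        if gene not in gene_set:
            raise DataError(
                f"panel {panel.name!r}, single-gene score {score!r}: "
                f"gene {gene!r} not in the expression matrix"
            )
        out[score] = expr.df.loc[gene]
    return out


def overall_immune(expr: ExpressionMatrix, overall_panel: list[str]) -> pd.Series:
    """Overall immune expression: per-sample median over the full immune panel
    (48 genes in the default panel)."""
    if not overall_panel:
        raise DataError("overall-immune panel is empty")
    tmp = MarkerPanel("overall", {"overall-immune": list(overall_panel)})
    return compute_scores(expr, tmp)["overall-immune"]


def dichotomize_q3(values: pd.Series) -> pd.Series:
    """Low/High at the cohort third quartile (High iff value > Q3).

    Q3 is the 0.75 linear-interpolation quantile of the non-missing values;
    at least 4 non-missing values are required for the cut to be meaningful.
    Missing values stay missing.
    """
    values = pd.Series(values, dtype=float)
    non_missing = values.dropna()
    if len(non_missing) == 0:
        raise DataError("cannot dichotomize: all values missing")
    if len(non_missing) < 4:
        raise DataError(
            f"cannot dichotomize: need >=4 non-missing values, got {len(non_missing)}"
        )
    q3 = float(np.quantile(non_missing.to_numpy(), 0.75))  # linear interpolation
    out = pd.Series(
        np.where(values > q3, "High", "Low"), index=values.index, dtype=object
    )
    out[values.isna()] = np.nan
    return out


# ---------------------------------------------------------------------------
# AGI composite
# ---------------------------------------------------------------------------

_TP53_VOCAB = {MUT_LIKE, WT_LIKE, MISSING}
_HRD_VOCAB = {HRD_POS, HRD_NEG, MISSING}


def agi_status(tp53: str, hrd: str) -> str:
    """OR-with-missingness truth table for a single (tp53, hrd) pair."""
    tp53 = MISSING if pd.isna(tp53) else tp53
    hrd = MISSING if pd.isna(hrd) else hrd
    if tp53 not in _TP53_VOCAB:
        raise DataError(f"tp53 call {tp53!r} not in {sorted(_TP53_VOCAB)}")
    if hrd not in _HRD_VOCAB:
        raise DataError(f"hrd call {hrd!r} not in {sorted(_HRD_VOCAB)}")
    if tp53 == MUT_LIKE or hrd == HRD_POS:
        return AGI
    if tp53 == WT_LIKE and hrd == HRD_NEG:
        return NGI
    return INDETERMINATE


def call_agi(tp53: pd.Series, hrd: pd.Series) -> pd.DataFrame:
    """Combine per-sample TP53 and HRD calls into the AGI composite.

    Inputs are label Series indexed by sample_id (``missing``/NaN allowed);
    the result has columns tp53, hrd, agi over the union of the two indexes.
    """
    idx = tp53.index.union(hrd.index)
    tp53 = tp53.reindex(idx).fillna(MISSING)
    hrd = hrd.reindex(idx).fillna(MISSING)
    agi = pd.Series(
        [agi_status(t, h) for t, h in zip(tp53, hrd)], index=idx, dtype=object
    )
    n_ind = int((agi == INDETERMINATE).sum())
    if n_ind:
        logger.info("AGI indeterminate for %d sample(s) (reason=missing_call)", n_ind)
    return pd.DataFrame({"tp53": tp53, "hrd": hrd, "agi": agi})
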