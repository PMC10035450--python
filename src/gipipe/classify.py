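"""Nearest-centroid training and classification.

Implements the similarity-to-centroid approach used for RNA-based TP53
functional status (Mut-like vs WT-like), HRD status (HRD+ vs HRD-) and the
three global immune classes: a sample is assigned the class whose centroid
profile it is most similar to, with Spearman rank correlation as the default
similarity (rank-based, hence robust to platform/scale differences), Pearson
and Euclidean selectable per centroid set.

Missing-gene policy: similarities are computed on the genes shared by the
sample and the centroid set; a sample observing fewer than ``min_gene_fraction``
of the centroid genes is called ``missing``. Exact similarity ties go to the
first tied class in the centroid set's declared class order and set
``tie_flag`` — deterministic and auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CentroidSet, DataError, ExpressionMatrix

logger = logging.getLogger("gipipe")

MISSING_LABEL = "missing"


def train_centroids(
    expr: ExpressionMatrix,
    labels: pd.Series | dict,
    *,
    signature_name: str = "custom",
    genes_per_class: int | str = "all",
    metric: str = "spearman",
    class_order: list[str] | None = None,
) -> CentroidSet:
    """Train per-class mean centroids, optionally on ANOVA-selected genes.

    Parameters
    ----------
    labels
        sample_id -> class label for the training samples. Every class must
        have at least one labeled sample; labels must reference samples
        present in ``expr``.
    genes_per_class
        ``"all"`` keeps every gene. A finite count ranks genes by a one-way
        ANOVA F statistic across the classes and keeps the union of the
        top-``genes_per_class`` genes per class.
    class_order
        Declared class order of the result (defines tie-breaking downstream);
        defaults to sorted label order.
    """
    labels = pd.Series(labels)
    unknown = set(labels.index) - set(expr.sample_ids)
    if unknown:
        raise DataError(f"labels reference unknown sample(s): {sorted(unknown)}")
    classes = class_order if class_order is not None else sorted(labels.unique())
    counts = labels.value_counts()
    empty = [c for c in classes if counts.get(c, 0) == 0]
    if empty:
        raise DataError(f"class(es) with zero training samples: {empty}")

    df = expr.df
    class_means = {c: df[labels.index[labels == c]].mean(axis=1) for c in classes}

    gene_ids = expr.gene_ids
    if genes_per_class != "all":
        k = int(genes_per_class)
        if k > len(gene_ids):
            warnings.warn(
                f"genes_per_class={k} exceeds the {len(gene_ids)} available genes; "
                "clamping",
                stacklevel=2,
            )
            k = len(gene_ids)
        f_stat = _anova_f(df, labels, classes)
        # one global separation ranking; the per-class top-k union equals top-k
        gene_ids = f_stat.sort_values(ascending=False, kind="stable").index[:k].tolist()

    values = np.vstack([class_means[c].loc[gene_ids].to_numpy() for c in classes])
    return CentroidSet(
        signature_name=signature_name,
        class_labels=list(classes),
        gene_ids=list(gene_ids),
        centroid_values=values,
        metric=metric,
    )


def _anova_f(df: pd.DataFrame, labels: pd.Series, classes) -> pd.Series:
    """Vectorised per-gene one-way ANOVA F across classes (NaN-safe)."""
    groups = [df[labels.index[labels == c]].to_numpy() for c in classes]
    ns = np.array([np.sum(~np.isnan(g), axis=1) for g in groups])  # classes x genes
    means = np.array([np.nanmean(g, axis=1) for g in groups])
    grand = np.nansum(means * ns, axis=0) / ns.sum(axis=0)
    ss_between = np.nansum(ns * (means - grand) ** 2, axis=0)
    ss_within = np.array(
        [np.nansum((g - m[:, None]) ** 2, axis=1) for g, m in zip(groups, means)]
    ).sum(axis=0)
    df_between = len(groups) - 1
    df_within = np.maximum(ns.sum(axis=0) - len(groups), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    return pd.Series(np.nan_to_num(f, nan=0.0, posinf=np.inf), index=df.index)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _similarities(x: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    """Similarity of one sample vector to each centroid row (higher = closer).

    Euclidean similarities are reported as negative distance so that argmax
    semantics are uniform across metrics.
    """
    if metric == "spearman":
        return np.array(
            [stats.spearmanr(x, c).statistic for c in centroids]
        )
    if metric == "pearson":
        return np.array([stats.pearsonr(x, c).statistic for c in centroids])
    if metric == "euclidean":
        return -np.sqrt(((centroids - x) ** 2).sum(axis=1))
    raise DataError(f"unknown metric {metric!r}")


def classify(
    expr: ExpressionMatrix,
    centroids: CentroidSet,
    *,
    min_gene_fraction: float = 0.5,
) -> pd.DataFrame:
    """Nearest-centroid call per sample.

    Returns a frame indexed by sample_id with columns ``label``, one
    ``sim_<class>`` per class, ``tie_flag`` and ``n_genes_used``. Samples
    observing fewer than ``min_gene_fraction`` of the centroid genes get
    label ``missing`` and NaN similarities.
    """
    shared = [g for g in centroids.gene_ids if g in set(expr.gene_ids)]
    if not shared:
        raise DataError(
            "no overlap between expression genes "
            f"(n={len(expr.gene_ids)}, e.g. {expr.gene_ids[:3]}) and centroid genes "
            f"(n={len(centroids.gene_ids)}, e.g. {centroids.gene_ids[:3]})"
        )
    cent_frame = centroids.as_frame().loc[shared]  # genes x classes
    sub = expr.df.loc[shared]
    n_centroid_genes = len(centroids.gene_ids)
    classes = centroids.class_labels

    if (
        not sub.isna().to_numpy().any()
        and len(shared) >= max(2, min_gene_fraction * n_centroid_genes)
    ):
        return _classify_complete(sub, cent_frame, centroids.metric, classes)

    records = []
    for sample in expr.sample_ids:
        x = sub[sample].to_numpy()
        ok = ~np.isnan(x)
        n_used = int(ok.sum())
        if n_used < min_gene_fraction * n_centroid_genes or n_used < 2:
            records.append(
                {"sample_id": sample, "label": MISSING_LABEL, "tie_flag": False,
                 "n_genes_used": n_used,
                 **{f"sim_{c}": np.nan for c in classes}}
            )
            continue
        sims = _similarities(x[ok], cent_frame.to_numpy()[ok].T, centroids.metric)
        best = np.nanmax(sims)
        tied = np.isclose(sims, best, rtol=0.0, atol=0.0)
        label = classes[int(np.argmax(tied))]  # first tied class in declared order
        records.append(
            {"sample_id": sample, "label": label, "tie_flag": bool(tied.sum() > 1),
             "n_genes_used": n_used,
             **{f"sim_{c}": s for c, s in zip(classes, sims)}}
        )
    return pd.DataFrame.from_records(records).set_index("sample_id")


def _classify_complete(
    sub: pd.DataFrame, cent_frame: pd.DataFrame, metric: str, classes: list[str]
) -> pd.DataFrame:
    """Vectorised path for matrices with no missing values: one matrix product
    instead of a per-sample loop. Numerically identical to the loop path."""
    x = sub.to_numpy()  # genes x samples
    c = cent_frame.to_numpy()  # genes x classes
    if metric in ("spearman", "pearson"):
        if metric == "spearman":
            x = np.apply_along_axis(stats.rankdata, 0, x)
            c = np.apply_along_axis(stats.rankdata, 0, c)
        xz = (x - x.mean(axis=0)) / x.std(axis=0)
        cz = (c - c.mean(axis=0)) / c.std(axis=0)
        sims = (xz.T @ cz) / x.shape[0]  # samples x classes
    else:  # euclidean, as negative distance
        sims = -np.sqrt(
            ((x[:, :, None] - c[:, None, :]) ** 2).sum(axis=0)
        )
    best = sims.max(axis=1, keepdims=True)
    tied = sims == best
    labels = [classes[i] for i in tied.argmax(axis=1)]
    out = pd.DataFrame(
        {"label": labels, "tie_flag": tied.sum(axis=1) > 1,
         "n_genes_used": x.shape[0]},
        index=pd.Index(sub.columns, name="sample_id"),
    )
    for j, cls in enumerate(classes):
        out[f"sim_{cls}"] = sims[:, j]
    return out


# ---------------------------------------------------------------------------
# Signature binding (classifier -> analysis vocabulary)
# ---------------------------------------------------------------------------


@dataclass
class SignatureConfig:
    """Binds a CentroidSet to the output vocabulary of one analysis signature,
    mapping centroid class labels to analysis labels by position."""

    centroids: CentroidSet
    vocabulary: list[str]
    min_gene_fraction: float = 0.5

    def __post_init__(self):
        if len(self.vocabulary) != len(self.centroids.class_labels):
            raise DataError(
                f"vocabulary {self.vocabulary} does not match the "
                f"{len(self.centroids.class_labels)} centroid classes "
                f"{self.centroids.class_labels}"
            )


def call_signature(expr: ExpressionMatrix, signature: SignatureConfig) -> pd.DataFrame:
    """Classify and relabel into the signature's analysis vocabulary."""
    calls = classify(
        expr, signature.centroids, min_gene_fraction=signature.min_gene_fraction
    )
    mapping = dict(zip(signature.centroids.class_labels, signature.vocabulary))
    calls["label"] = calls["label"].map(lambda l: mapping.get(l, l))
    calls = calls.rename(
        columns={f"sim_{old}": f"sim_{new}" for old, new in mapping.items()}
    )
    n_missing = int((calls["label"] == MISSING_LABEL).sum())
    if n_missing:
        logger.info(
            "signature %s: %d sample(s) uncallable (reason=insufficient_genes)",
            signature.centroids.signature_name, n_missing,
        )
    return calls
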