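"""Domain types and tabular readers/writers shared by every pipeline stage.

Containers are thin wrappers around pandas objects so downstream stages can
use ordinary DataFrame idioms, while construction enforces the invariants the
pipeline relies on (unique identifiers, declared categorical vocabularies,
bounded missingness).

File formats: expression matrices are genes x samples TSV; sample annotations
are CSV with a header; marker panels are JSON; centroid sets are TSV with
``#key=value`` header comment lines carrying the similarity metric, the
signature name and the class order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gipipe")

MISSING_TOKENS = ("", "NA", "NaN", "nan")

#: declared categorical vocabularies; config-level so non-default cohorts load
#: without code changes
DEFAULT_VOCAB: dict[str, tuple[str, ...]] = {
    "race": ("Black", "non-Black"),
    "er_status": ("positive", "negative"),
    "stage": ("I", "II", "III", "IV"),
}

ANNOTATION_COLUMNS = (
    "sample_id",
    "age",
    "race",
    "er_status",
    "stage",
    "recurrence_time",
    "recurrence_event",
)


class DataError(ValueError):
    """Raised when an input file violates a load-time invariant."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Normalized log-scale expression, genes x samples.

    Values may be missing (NaN); a gene with more than ``max_missing_fraction``
    missing values is rejected at construction. Scale (log2 vs natural log) is
    treated as opaque: classification is rank-based and quartile cuts are
    within-cohort, both invariant under monotone transforms.
    """

    def __init__(self, values: pd.DataFrame, *, max_missing_fraction: float = 0.5):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene id(s): {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dupes}")
        values = values.astype(float)
        with np.errstate(invalid="ignore"):
            bad = np.isinf(values.to_numpy())
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataError(
                f"non-finite expression value at gene {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        if values.shape[1] > 0:
            missing_frac = values.isna().mean(axis=1)
            too_missing = missing_frac[missing_frac > max_missing_fraction]
            if len(too_missing):
                raise DataError(
                    "gene(s) exceed the missing-value threshold "
                    f"({max_missing_fraction:.0%}): {too_missing.index.tolist()}"
                )
        self._df = values

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample(self, sample_id: str) -> pd.Series:
        return self._df[sample_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


# ---------------------------------------------------------------------------
# MarkerPanel and CentroidSet
# ---------------------------------------------------------------------------


@dataclass
class MarkerPanel:
    """Cell-type marker gene lists plus single-gene scores.

    ``cell_type_to_genes`` maps a score name (B-cell, CD8 T cell, adaptive,
    innate, overall-immune, ...) to a non-empty gene list; single-gene scores
    (PD-L1 -> CD274, CD8 -> CD8A) pass one gene's value through unchanged.
    """

    name: str
    cell_type_to_genes: dict[str, list[str]]
    single_gene_scores: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for score, genes in self.cell_type_to_genes.items():
            if not genes:
                raise DataError(f"panel {self.name!r}: empty gene list for {score!r}")

    @property
    def score_names(self) -> list[str]:
        return list(self.cell_type_to_genes) + list(self.single_gene_scores)


@dataclass
class CentroidSet:
    """Per-class centroid profiles for nearest-centroid classification.

    Class order is part of the object identity: it defines tie-breaking and
    round-trips through serialization.
    """

    signature_name: str
    class_labels: list[str]
    gene_ids: list[str]
    centroid_values: np.ndarray  # classes x genes
    metric: str = "spearman"

    VALID_METRICS = ("spearman", "pearson", "euclidean")

    def __post_init__(self):
        self.centroid_values = np.asarray(self.centroid_values, dtype=float)
        if len(self.class_labels) < 2:
            raise DataError(
                f"centroid set {self.signature_name!r} needs >=2 classes, "
                f"got {self.class_labels}"
            )
        if len(set(self.class_labels)) != len(self.class_labels):
            raise DataError(f"duplicate class labels in {self.signature_name!r}")
        if self.centroid_values.shape != (len(self.class_labels), len(self.gene_ids)):
            raise DataError(
                f"centroid matrix shape {self.centroid_values.shape} does not match "
                f"{len(self.class_labels)} classes x {len(self.gene_ids)} genes"
            )
        if self.metric not in self.VALID_METRICS:
            raise DataError(
                f"unknown metric {self.metric!r}; expected one of {self.VALID_METRICS}"
            )

    def as_frame(self) -> pd.DataFrame:
        """Genes x classes frame (column order = declared class order)."""
        return pd.DataFrame(
            self.centroid_values.T, index=self.gene_ids, columns=self.class_labels
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(path, *, max_missing_fraction: float = 0.5) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # transposed-orientation heuristic: clearer error, never an auto-fix
    if header and header[0].strip().lower() in {"sample_id", "sample", "samples"}:
        raise DataError(
            f"{path.name} looks transposed (first header cell "
            f"{header[0]!r} suggests samples in rows); expected genes x samples"
        )
    sample_ids = header[1:]
    seen: set[str] = set()
    dupes = [s for s in sample_ids if s in seen or seen.add(s)]
    if dupes:
        raise DataError(f"duplicate sample column(s) in {path.name}: {sorted(set(dupes))}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    numeric = raw.replace(list(MISSING_TOKENS), np.nan).apply(
        lambda col: pd.to_numeric(col, errors="coerce")
    )
    # a cell that failed to parse is NaN in numeric but not a missing token in raw
    bad = numeric.isna() & ~raw.isin(MISSING_TOKENS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell {raw.iat[r, c]!r} at gene {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path.name}"
        )
    return ExpressionMatrix(numeric, max_missing_fraction=max_missing_fraction)


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_annotations(path, *, vocab: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Read a sample annotation CSV and validate categorical vocabularies.

    Categorical levels outside the declared vocabulary raise; missing values
    ("" or NA) are kept as NaN — exclusions happen downstream, never at load,
    and every downstream exclusion is logged with a reason code.
    """
    vocab = dict(DEFAULT_VOCAB, **(vocab or {}))
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise DataError(f"annotation file missing column(s): {sorted(missing_cols)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample id(s) in annotations: {dupes}")
    for col, levels in vocab.items():
        observed = df[col].dropna().unique()
        unknown = sorted(set(observed) - set(levels))
        if unknown:
            raise DataError(
                f"unknown {col} level(s) {unknown}; allowed levels: {list(levels)}"
            )
    neg_time = df["recurrence_time"].dropna() < 0
    if neg_time.any():
        raise DataError("recurrence_time must be >= 0")
    event_no_time = (df["recurrence_event"] == 1) & df["recurrence_time"].isna()
    if event_no_time.any():
        raise DataError(
            f"recurrence event without a time for sample(s): "
            f"{df.loc[event_no_time, 'sample_id'].tolist()}"
        )
    return df


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def read_panel(path) -> MarkerPanel:
    """Read a marker panel JSON: {name, cell_type_to_genes, single_gene_scores}."""
    with Path(path).open() as fh:
        payload = json.load(fh)
    return MarkerPanel(
        name=payload["name"],
        cell_type_to_genes={k: list(v) for k, v in payload["cell_type_to_genes"].items()},
        single_gene_scores=dict(payload.get("single_gene_scores", {})),
    )


def write_panel(panel: MarkerPanel, path) -> None:
    payload = {
        "name": panel.name,
        "cell_type_to_genes": panel.cell_type_to_genes,
        "single_gene_scores": panel.single_gene_scores,
    }
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_centroids(path) -> CentroidSet:
    """Read a centroid TSV with ``#metric=``/``#signature=`` header comments.

    Body: genes as rows, classes as columns; column order is the declared
    class order and round-trips exactly.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                body_start += 1
            else:
                break
    if "metric" not in meta:
        raise DataError(f"{path.name}: missing '#metric=' header line")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=body_start)
    return CentroidSet(
        signature_name=meta.get("signature", path.stem),
        class_labels=df.columns.tolist(),
        gene_ids=df.index.astype(str).tolist(),
        centroid_values=df.to_numpy().T,
        metric=meta["metric"],
    )


def write_centroids(centroids: CentroidSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"#metric={centroids.metric}\n")
        fh.write(f"#signature={centroids.signature_name}\n")
        frame = centroids.as_frame()
        frame.index.name = "gene_id"
        frame.to_csv(fh, sep="\t")
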