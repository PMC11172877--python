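"""Nearest-centroid molecular subtyping and subtype-plasticity statistics.

A sample is assigned to the intrinsic subtype whose centroid profile it
correlates with best (Spearman by default, the canonical PAM50
convention).  Plasticity between matched samples (pre/post therapy, or
primary tumor vs metastases) is summarized as a K×K transition matrix —
rows are the earlier/primary label, columns the later/metastatic label —
with retention fractions per class and overall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    InsufficientOverlapError,
    LabelError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "SubtypeCall",
    "TransitionMatrix",
    "RetentionStats",
    "validate_centroids",
    "classify_nearest_centroid",
    "classify_cohort",
    "transition_matrix",
    "retention_stats",
    "per_primary_transitions",
]

PAM50_CLASSES = ("Basal", "HER2", "LumA", "LumB", "Normal")


def validate_centroids(centroids: pd.DataFrame) -> pd.DataFrame:
    """Check a genes × classes centroid matrix."""
    if centroids.shape[1] < 2:
        raise ValidationError("centroid matrix needs at least two classes")
    if centroids.columns.has_duplicates:
        raise ValidationError("duplicate class names in centroid matrix")
    if centroids.index.has_duplicates:
        raise ValidationError("duplicate gene ids in centroid matrix")
    const = [c for c in centroids.columns if centroids[c].nunique() <= 1]
    if const:
        raise ValidationError(f"constant centroid profile(s): {const}")
    return centroids.astype(float)


@dataclass
class SubtypeCall:
    sample_id: str
    label: str
    correlations: pd.Series  # per-class correlation, in class order
    margin: float  # best minus second-best correlation, >= 0
    n_genes_used: int
    tie: bool = False


def classify_nearest_centroid(
    sample: pd.Series,
    centroids: pd.DataFrame,
    correlation_kind: str = "spearman",
    min_genes: int = 30,
) -> SubtypeCall:
    """Assign a sample to the subtype with the highest centroid correlation.

    Genes missing from the sample are dropped symmetrically from every
    centroid and only counted genes enter the correlation; fewer than
    ``min_genes`` overlapping genes is an error.  Exact correlation ties
    are broken deterministically towards the class listed first, with a
    warning.
    """
    centroids = validate_centroids(centroids)
    genes = [g for g in centroids.index if g in sample.index and np.isfinite(sample[g])]
    if len(genes) < min_genes:
        raise InsufficientOverlapError(
            f"sample {sample.name!r} shares only {len(genes)} genes with the "
            f"centroids; minimum is {min_genes}"
        )
    v = sample[genes].to_numpy(float)
    if np.unique(v).size < 2:
        raise UndefinedCorrelationError(
            f"sample {sample.name!r} is constant over the centroid genes"
        )
    sub = centroids.loc[genes]
    if correlation_kind == "pearson":
        rs = np.array([stats.pearsonr(v, sub[c].to_numpy()).statistic for c in sub.columns])
    elif correlation_kind == "spearman":
        rs = np.array([stats.spearmanr(v, sub[c].to_numpy()).statistic for c in sub.columns])
    else:
        raise ParameterError(f"unknown correlation kind {correlation_kind!r}")
    corr = pd.Series(rs, index=centroids.columns)
    best = float(np.nanmax(rs))
    winners = np.nonzero(np.isclose(rs, best, rtol=0.0, atol=1e-12))[0]
    tie = len(winners) > 1
    if tie:
        warnings.warn(
            f"sample {sample.name!r}: correlation tie between "
            f"{[centroids.columns[i] for i in winners]}; assigning the first",
            stacklevel=2,
        )
    label = str(centroids.columns[winners[0]])
    others = np.delete(rs, winners[0])
    margin = 0.0 if tie else float(best - np.nanmax(others))
    return SubtypeCall(
        sample_id=str(sample.name),
        label=label,
        correlations=corr,
        margin=margin,
        n_genes_used=len(genes),
        tie=tie,
    )


def classify_cohort(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    correlation_kind: str = "spearman",
    min_genes: int = 30,
    median_center: bool = True,
) -> pd.DataFrame:
    """Classify every sample of a cohort.

    ``median_center`` subtracts each gene's cohort median before
    correlation (centroid classifiers assume centered data); switch off
    for data already centered.
    """
    m = matrix
    if median_center:
        m = matrix.sub(matrix.median(axis=1), axis=0)
    calls = [
        classify_nearest_centroid(m[s], centroids, correlation_kind, min_genes)
        for s in m.columns
    ]
    out = pd.DataFrame(
        {
            "label": [c.label for c in calls],
            "margin": [c.margin for c in calls],
            "n_genes_used": [c.n_genes_used for c in calls],
            "tie": [c.tie for c in calls],
        },
        index=pd.Index([c.sample_id for c in calls], name="sample_id"),
    )
    corr = pd.DataFrame(
        [c.correlations for c in calls],
        index=out.index,
    ).add_prefix("r_")
    return pd.concat([out, corr], axis=1)


@dataclass
class TransitionMatrix:
    """Paired-label count matrix; rows = first timepoint, columns = second."""

    counts: pd.DataFrame

    def __post_init__(self):
        c = self.counts
        if not c.index.equals(c.columns):
            raise ValidationError("transition matrix rows and columns must share class names")
        if (c.to_numpy() < 0).any():
            raise ValidationError("transition counts must be non-negative")
        self.counts = c.astype(int)

    @property
    def class_names(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts.to_numpy()))


def transition_matrix(
    paired_calls: Iterable[tuple[str, str]],
    class_names: Sequence[str],
) -> TransitionMatrix:
    """Count matrix of paired subtype calls.

    ``counts[i, j]`` = number of pairs labelled class i at the first
    timepoint and class j at the second.  Any label outside
    ``class_names`` raises :class:`LabelError` naming the offender.
    """
    names = list(class_names)
    pos = {c: i for i, c in enumerate(names)}
    counts = np.zeros((len(names), len(names)), dtype=int)
    for l1, l2 in paired_calls:
        for lab in (l1, l2):
            if lab not in pos:
                raise LabelError(f"unknown subtype label {lab!r}; classes are {names}")
        counts[pos[l1], pos[l2]] += 1
    frame = pd.DataFrame(counts, index=pd.Index(names), columns=pd.Index(names))
    return TransitionMatrix(counts=frame)


@dataclass
class RetentionStats:
    overall_retained_fraction: float
    per_class_retention: pd.Series  # diagonal / row sum; NaN for empty rows
    per_class_switched: pd.Series  # off-diagonal row counts
    modal_destination: pd.Series  # most common off-diagonal destination; None if none


def retention_stats(tm: TransitionMatrix) -> RetentionStats:
    """Retention/switching summary of a transition matrix."""
    c = tm.counts.to_numpy(float)
    n = c.sum()
    if n < 1:
        raise DegenerateInputError("transition matrix is empty")
    diag = np.diag(c)
    rowsum = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(rowsum > 0, diag / rowsum, np.nan)
    switched = rowsum - diag
    modal = []
    for i, row in enumerate(c):
        off = row.copy()
        off[i] = 0
        modal.append(tm.class_names[int(off.argmax())] if off.sum() > 0 else None)
    names = pd.Index(tm.class_names)
    return RetentionStats(
        overall_retained_fraction=float(diag.sum() / n),
        per_class_retention=pd.Series(per_class, index=names),
        per_class_switched=pd.Series(switched.astype(int), index=names),
        modal_destination=pd.Series(modal, index=names, dtype=object),
    )


def per_primary_transitions(
    patient_records: Mapping[str, tuple[str, Sequence[str]]],
    class_names: Sequence[str],
) -> tuple[pd.DataFrame, TransitionMatrix]:
    """Per-patient primary→metastasis transitions plus the aggregate matrix.

    ``patient_records`` maps patient id to ``(primary_label,
    [metastasis_labels])``; every patient must have at least one
    metastasis.  The aggregate equals :func:`transition_matrix` applied to
    the flattened (primary, metastasis) pair list — each metastasis is one
    pair, so patients are weighted by their metastasis count.
    """
    names = list(class_names)
    rows = []
    pairs: list[tuple[str, str]] = []
    for patient, (primary, mets) in patient_records.items():
        mets = list(mets)
        if not mets:
            raise ParameterError(f"patient {patient!r} has no metastasis labels")
        if primary not in names:
            raise LabelError(f"unknown primary label {primary!r} for patient {patient!r}")
        row = {"patient": patient, "primary": primary, "n_metastases": len(mets)}
        counts = {c: 0 for c in names}
        for m in mets:
            if m not in names:
                raise LabelError(f"unknown metastasis label {m!r} for patient {patient!r}")
            counts[m] += 1
            pairs.append((primary, m))
        row.update(counts)
        row["retained"] = counts[primary]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("patient")
    return table, transition_matrix(pairs, names)
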