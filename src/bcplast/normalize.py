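"""RNA-seq count normalization and qPCR concordance.

Three library-normalization schemes, implemented with explicit parameters:

* **median-of-ratios** size factors (the DESeq scheme): each sample's
  factor is the median, over genes with an all-nonzero row, of its counts
  divided by the per-gene geometric-mean pseudo-reference;
* **FPKM**: count / (kilobases of transcript × millions of mapped reads);
* **TMM**: a doubly trimmed (by log-ratio M and log-abundance A),
  inverse-variance-weighted mean of per-gene log ratios to a reference
  sample, exponentiated and renormalized so factors multiply to 1.

Plus the −ΔΔCt transform for qPCR panels and the per-gene group
comparison (means, Welch t-test, direction) used to ask whether qPCR and
RNA-seq move the same way between treatment groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    BcplastError,
    DegenerateInputError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "size_factors_median_ratio",
    "fpkm",
    "tmm_factors",
    "neg_ddct",
    "group_mean_ttest",
    "direction_concordance",
    "spearman_correlate",
]


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    c = counts.to_numpy(float)
    if (c < 0).any() or not np.isfinite(c).all():
        raise ValidationError("counts must be finite and non-negative")
    return c


def size_factors_median_ratio(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    Genes with a zero count in any sample are excluded from the
    pseudo-reference.  Returns ``(factors, counts / factors)``.
    """
    c = _check_counts(counts)
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise DegenerateInputError(
            "no gene has nonzero counts in every sample; filter genes or add a pseudocount"
        )
    logc = np.log(c[all_nonzero])
    log_ref = logc.mean(axis=1)  # log geometric mean per gene
    log_factors = np.median(logc - log_ref[:, None], axis=0)
    factors = pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")
    return factors, counts.div(factors, axis=1)


def fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM_gs = count_gs / (length_g / 1e3) / (library_s / 1e6)``.
    """
    c = _check_counts(counts)
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:5])
        raise ValidationError(f"gene length missing for: {missing}")
    if (lengths < 1).any():
        raise ParameterError("gene lengths must be >= 1 bp")
    totals = c.sum(axis=0)
    if (totals <= 0).any():
        bad = list(counts.columns[totals <= 0])
        raise DegenerateInputError(f"zero library total for sample(s): {bad}")
    kb = lengths.to_numpy(float) / 1e3
    mill = totals / 1e6
    return pd.DataFrame(
        c / kb[:, None] / mill[None, :], index=counts.index, columns=counts.columns
    )


def tmm_factors(
    counts: pd.DataFrame,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample against the reference, per-gene log2 ratios M and
    log2 abundances A are computed on genes nonzero in both; the extreme
    ``trim_m`` / ``trim_a`` fractions of each are trimmed away and the
    factor is the precision-weighted mean of the remaining M,
    exponentiated.  Factors are renormalized to multiply to 1, and the
    composition-robust trimming makes them track true library scaling
    even when a minority of genes is strongly shifted.

    The default reference is the sample whose upper-quartile count is
    closest to the mean upper quartile.
    """
    c = _check_counts(counts)
    n_samples = counts.shape[1]
    if n_samples < 2:
        raise ParameterError("TMM needs at least two samples")
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ParameterError("trim fractions must lie in [0, 0.5)")
    if reference is None:
        uq = np.percentile(c, 75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in counts.columns:
            raise ParameterError(f"reference sample {reference!r} not in matrix")
        ref_idx = counts.columns.get_loc(reference)
    ref = c[:, ref_idx]

    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref_idx:
            continue
        s = c[:, j]
        both = (s > 0) & (ref > 0)
        if not both.any():
            raise DegenerateInputError("no gene expressed in both sample and reference")
        m = np.log2(s[both] / ref[both])
        a = 0.5 * np.log2(s[both] * ref[both])
        keep = np.ones(len(m), dtype=bool)
        if trim_m > 0:
            lo, hi = np.quantile(m, [trim_m, 1.0 - trim_m])
            keep &= (m >= lo) & (m <= hi)
        if trim_a > 0:
            lo, hi = np.quantile(a, [trim_a, 1.0 - trim_a])
            keep &= (a >= lo) & (a <= hi)
        if not keep.any():
            raise DegenerateInputError("no genes survive TMM trimming")
        # delta-method variance of a log count ratio
        w = 1.0 / s[both][keep] + 1.0 / ref[both][keep]
        log_factors[j] = float(np.sum(m[keep] / w) / np.sum(1.0 / w))

    log_factors -= log_factors.mean()  # product of factors = 1
    return pd.Series(2.0**log_factors, index=counts.columns, name="tmm_factor")


def neg_ddct(
    ct: pd.DataFrame,
    housekeeping_gene: str,
    reference_samples,
) -> pd.DataFrame:
    """−ΔΔCt relative quantification of a qPCR panel.

    ``ΔCt = Ct_gene − Ct_housekeeping`` per sample; ``ΔΔCt`` subtracts the
    mean ΔCt of the reference-sample group per gene; the negation makes
    higher values mean higher expression (one unit ≈ one doubling).
    The housekeeping row is removed from the output.
    """
    if housekeeping_gene not in ct.index:
        raise ValidationError(f"housekeeping gene {housekeeping_gene!r} not in Ct table")
    hk = ct.loc[housekeeping_gene]
    bad = list(ct.columns[~np.isfinite(hk.to_numpy(float))])
    if bad:
        raise ValidationError(f"missing housekeeping Ct for sample(s): {bad}")
    ref = [s for s in reference_samples]
    unknown = [s for s in ref if s not in ct.columns]
    if unknown or not ref:
        raise ValidationError(f"invalid reference group (unknown samples: {unknown})")
    dct = ct.drop(index=housekeeping_gene).sub(hk, axis=1)
    ddct = dct.sub(dct[ref].mean(axis=1), axis=0)
    return -ddct


def group_mean_ttest(
    values: pd.DataFrame,
    group_labels: pd.Series,
    before_label: str | None = None,
) -> pd.DataFrame:
    """Per-gene group means and Welch t-test between two groups.

    ``group_labels`` maps sample id to one of exactly two labels.  The
    before-treatment group is ``before_label`` if given, otherwise ``BC``
    when the labels are the conventional BC/AC pair, otherwise the first
    label in sorted order.  Returns a frame with ``mean_bc``, ``mean_ac``,
    ``t_p`` and ``direction`` (sign of after − before) per gene.
    """
    labels = group_labels.reindex(values.columns)
    if labels.isna().any():
        raise ValidationError(
            f"no group label for sample(s): {list(values.columns[labels.isna()][:5])}"
        )
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ParameterError(f"need exactly two groups, got {groups}")
    if before_label is None:
        before_label = "BC" if set(groups) == {"BC", "AC"} else groups[0]
    if before_label not in groups:
        raise ParameterError(f"before_label {before_label!r} not among groups {groups}")
    gb = before_label
    ga = groups[0] if groups[1] == gb else groups[1]
    rows = []
    for gene, row in values.iterrows():
        b = row[labels[labels == gb].index].dropna().to_numpy(float)
        a = row[labels[labels == ga].index].dropna().to_numpy(float)
        if len(b) < 2 or len(a) < 2:
            raise ParameterError(f"gene {gene!r}: each group needs at least two samples")
        diff = a.mean() - b.mean()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {"gene_id": gene, "mean_bc": b.mean(), "mean_ac": a.mean(),
             "t_p": p, "direction": int(np.sign(diff))}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _directions(rows: pd.DataFrame) -> pd.Series:
    if "mean_bc" not in rows.columns or "mean_ac" not in rows.columns:
        raise ValidationError("concordance rows need mean_bc and mean_ac columns")
    return np.sign(rows["mean_ac"] - rows["mean_bc"]).astype(int)


def direction_concordance(
    rows_a: pd.DataFrame, rows_b: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Per-gene direction agreement between two group-comparison tables.

    A shared gene agrees iff the sign of (after − before) matches; a zero
    difference only matches another zero.  Returns the per-gene table and
    the number of concordant genes.
    """
    shared = rows_a.index.intersection(rows_b.index)
    if len(shared) == 0:
        raise BcplastError("no shared genes between the two tables")
    da = _directions(rows_a.loc[shared])
    db = _directions(rows_b.loc[shared])
    out = pd.DataFrame(
        {"direction_a": da, "direction_b": db, "concordant": (da == db)}, index=shared
    )
    return out, int(out["concordant"].sum())


def spearman_correlate(values_a, values_b) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) of paired observations."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ParameterError("paired vectors must have equal length")
    if len(a) < 4:
        raise ParameterError("need at least 4 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)
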