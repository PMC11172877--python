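"""EMT/stemness scoring via template correlation (Delta(r)).

Each sample's expression over a stem/non-stem signature gene list is
correlated with two template profiles: a non-stem/epithelial pole (NS/E)
and a stem/mesenchymal pole (CS/M).  The score is the difference

    Delta(r) = r_CSM − r_NSE,

so negative values indicate a more epithelial, non-stem-like phenotype and
positive values a more mesenchymal, stem-like one.  Cohort-level shifts
(e.g. pre- vs post-chemotherapy) are tested with paired or Welch t-tests.

The published 15-gene signature's template values are not bundled here;
templates are an input (see :func:`bcplast.simulate.synthetic_templates`
for a documented synthetic stand-in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientOverlapError,
    PairingError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "StemnessTemplates",
    "DeltaRScore",
    "ShiftTestResult",
    "delta_r",
    "cohort_delta_r",
    "cohort_shift_test",
]


def _as_frame(profile, name: str) -> pd.DataFrame:
    if isinstance(profile, pd.Series):
        profile = profile.to_frame(name)
    if not isinstance(profile, pd.DataFrame):
        raise ValidationError(f"{name} template must be a pandas Series or DataFrame")
    return profile.astype(float)


@dataclass
class StemnessTemplates:
    """NS/E and CS/M template profiles over a shared signature gene list.

    Either pole may be a single profile or a multi-column matrix (e.g. one
    column per reference sample); multi-column poles are summarized by the
    mean (or max) of per-column correlations.
    """

    nse: pd.DataFrame
    csm: pd.DataFrame

    def __post_init__(self):
        self.nse = _as_frame(self.nse, "NS/E")
        self.csm = _as_frame(self.csm, "CS/M")
        if not self.nse.index.equals(self.csm.index):
            raise ValidationError("NS/E and CS/M templates must share the same gene list")
        for name, frame in (("NS/E", self.nse), ("CS/M", self.csm)):
            if frame.shape[1] < 1:
                raise ValidationError(f"{name} template has no columns")
            if (frame.nunique(axis=0) <= 1).any():
                raise ValidationError(f"{name} template contains a constant column")

    @property
    def gene_list(self) -> list[str]:
        return list(self.nse.index)

    def swapped(self) -> "StemnessTemplates":
        """Templates with the two poles exchanged (negates every delta)."""
        return StemnessTemplates(nse=self.csm.copy(), csm=self.nse.copy())


@dataclass
class DeltaRScore:
    sample_id: str
    r_nse: float
    r_csm: float
    delta: float
    n_genes_used: int
    n_dropped: int


def _corr(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif kind == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ParameterError(f"unknown correlation kind {kind!r}")
    return float(r)


def _pole_corr(sample: np.ndarray, frame: pd.DataFrame, kind: str, combine: str) -> float:
    rs = [_corr(sample, frame[c].to_numpy(), kind) for c in frame.columns]
    if combine == "mean":
        return float(np.mean(rs))
    if combine == "max":
        return float(np.max(rs))
    raise ParameterError(f"unknown combine rule {combine!r}")


def delta_r(
    sample: pd.Series,
    templates: StemnessTemplates,
    correlation_kind: str = "pearson",
    combine: str = "mean",
) -> DeltaRScore:
    """Delta(r) score of one sample.

    Genes missing from the sample (absent or NaN) are dropped symmetrically
    from both templates and counted in ``n_dropped``; fewer than 3
    overlapping genes, or a sample constant over the overlap, is an error.
    """
    genes = [g for g in templates.gene_list if g in sample.index and np.isfinite(sample[g])]
    n_dropped = len(templates.gene_list) - len(genes)
    if len(genes) < 3:
        raise InsufficientOverlapError(
            f"only {len(genes)} signature gene(s) present in sample "
            f"{sample.name!r}; need at least 3"
        )
    v = sample[genes].to_numpy(float)
    if np.unique(v).size < 2:
        raise UndefinedCorrelationError(
            f"sample {sample.name!r} is constant over the signature genes"
        )
    nse = templates.nse.loc[genes]
    csm = templates.csm.loc[genes]
    r_nse = _pole_corr(v, nse, correlation_kind, combine)
    r_csm = _pole_corr(v, csm, correlation_kind, combine)
    return DeltaRScore(
        sample_id=str(sample.name),
        r_nse=r_nse,
        r_csm=r_csm,
        delta=r_csm - r_nse,
        n_genes_used=len(genes),
        n_dropped=n_dropped,
    )


def cohort_delta_r(
    matrix: pd.DataFrame,
    templates: StemnessTemplates,
    correlation_kind: str = "pearson",
    combine: str = "mean",
) -> pd.DataFrame:
    """Delta(r) for every column (sample) of an expression matrix."""
    records = [
        delta_r(matrix[s], templates, correlation_kind, combine) for s in matrix.columns
    ]
    out = pd.DataFrame(
        {
            "r_nse": [r.r_nse for r in records],
            "r_csm": [r.r_csm for r in records],
            "delta": [r.delta for r in records],
            "n_genes_used": [r.n_genes_used for r in records],
            "n_dropped": [r.n_dropped for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )
    return out


@dataclass
class ShiftTestResult:
    mean_before: float
    mean_after: float
    mean_difference: float  # after − before
    t_statistic: float
    p_value: float
    n_before: int
    n_after: int
    paired: bool


def cohort_shift_test(scores_before, scores_after, paired: bool = False) -> ShiftTestResult:
    """Test a cohort-level shift in Delta(r) (or any score).

    Unpaired mode uses the Welch two-sample t-test; paired mode a paired
    t-test with ``scores_before[i]`` matched to ``scores_after[i]``.  The
    reported mean difference is after − before (positive = shift towards
    the mesenchymal/stem pole).
    """
    b = np.asarray(scores_before, dtype=float)
    a = np.asarray(scores_after, dtype=float)
    if len(b) < 2 or len(a) < 2:
        raise ParameterError("need at least two scores per arm")
    if paired and len(b) != len(a):
        raise PairingError(f"paired arms differ in size: {len(b)} vs {len(a)}")

    if paired:
        d = a - b
        if np.allclose(d, d[0]):
            # degenerate: constant differences
            t = 0.0 if d[0] == 0 else float(np.sign(d[0]) * np.inf)
            p = 1.0 if d[0] == 0 else 0.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            diff = a.mean() - b.mean()
            t = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
            p = 1.0 if diff == 0 else 0.0
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
    return ShiftTestResult(
        mean_before=float(b.mean()),
        mean_after=float(a.mean()),
        mean_difference=float(a.mean() - b.mean()),
        t_statistic=t,
        p_value=p,
        n_before=len(b),
        n_after=len(a),
        paired=paired,
    )
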