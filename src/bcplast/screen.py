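"""Per-gene survival screening (the USAT consensus).

For every gene, three survival tests are run on the same cohort:

1. a *maximally selected rank statistic* finds the expression cutpoint that
   best separates survival, with a p-value adjusted for the maximal
   selection (Brownian-bridge approximation of Lausen & Schumacher, 1992);
2. a univariate Cox proportional-hazards regression on the (by default
   continuous) expression value, Efron tie handling, Wald p;
3. a log-rank test on the two groups induced by the maxstat cutpoint.

A gene is *selected* when all three p-values fall below ``alpha`` (no
multiple-testing correction by default, matching the original procedure; a
Benjamini–Hochberg variant can be switched on).  Genes with a hazard ratio
above 1 are "up in the bad-survival group", below 1 "down".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    NoValidCutpointError,
    ParameterError,
)

__all__ = [
    "ScreenConfig",
    "MaxstatResult",
    "CoxResult",
    "logrank_test",
    "logrank_scores",
    "maxstat_cutpoint",
    "cox_univariate",
    "usat_screen",
    "gene_list_overlap",
    "OverlapTable",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    """Tunable knobs of the consensus screen.

    alpha
        Per-test significance threshold (0.05 in the original procedure).
    quantile_bounds
        Candidate cutpoints are restricted to expression values whose
        low-group proportion lies in this band; (0.10, 0.90) keeps at least
        10% of samples on each side of every split.
    ties_method
        Cox partial-likelihood tie handling, ``"efron"`` or ``"breslow"``.
    cox_covariate
        ``"continuous"`` fits Cox on the raw expression value (default);
        ``"dichotomized"`` on the 0/1 indicator induced by the maxstat
        cutpoint.
    maxstat_pmethod
        ``"lau92"`` analytic approximation or ``"permutation"`` (seeded).
    bh_correction
        If True, selection uses Benjamini–Hochberg adjusted p-values per
        test instead of raw ones.  Off by default.
    """

    alpha: float = 0.05
    quantile_bounds: tuple[float, float] = (0.10, 0.90)
    ties_method: str = "efron"
    cox_covariate: str = "continuous"
    maxstat_pmethod: str = "lau92"
    n_permutations: int = 1000
    permutation_seed: int = 0
    bh_correction: bool = False

    def __post_init__(self):
        q1, q2 = self.quantile_bounds
        if not (0.0 < q1 < q2 < 1.0):
            raise ParameterError(f"quantile_bounds must satisfy 0 < q1 < q2 < 1, got {self.quantile_bounds}")
        if not (0.0 <= self.alpha < 1.0):
            raise ParameterError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.ties_method not in ("efron", "breslow"):
            raise ParameterError(f"unknown ties_method {self.ties_method!r}")
        if self.cox_covariate not in ("continuous", "dichotomized"):
            raise ParameterError(f"unknown cox_covariate {self.cox_covariate!r}")
        if self.maxstat_pmethod not in ("lau92", "permutation"):
            raise ParameterError(f"unknown maxstat_pmethod {self.maxstat_pmethod!r}")


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


def logrank_test(group_labels, time, event) -> tuple[float, float]:
    """Multi-group log-rank test.

    At every distinct event time a K×2 table is formed; observed minus
    expected event counts per group are summed and standardized with the
    hypergeometric variance.  The two-group case reduces to the classical
    statistic; K groups give a chi-square on K−1 degrees of freedom.

    Returns ``(chi_square_statistic, p_value)``.
    """
    g = np.asarray(group_labels)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (len(g) == len(t) == len(e)):
        raise ParameterError("group_labels, time and event must have equal length")
    labels = np.unique(g)
    k = len(labels)
    if k < 2:
        raise DegenerateInputError("log-rank test needs at least two non-empty groups")
    if e.sum() < 1:
        raise DegenerateInputError("log-rank test needs at least one event")

    gidx = np.searchsorted(labels, g)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = int(at_risk.sum())
        dying = (t == tt) & (e == 1)
        d = int(dying.sum())
        ng = np.bincount(gidx[at_risk], minlength=k).astype(float)
        dg = np.bincount(gidx[dying], minlength=k).astype(float)
        O += dg
        E += d * ng / n
        if n > 1:
            frac = ng / n
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))

    u = (O - E)[:-1]
    vsub = V[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(vsub) @ u)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# maximally selected rank statistic
# ---------------------------------------------------------------------------


def logrank_scores(time, event) -> np.ndarray:
    """Log-rank (Savage-type) scores for censored data.

    ``a_i = event_i − Λ̂(time_i)`` with Λ̂ the Nelson–Aalen cumulative
    hazard.  The scores sum to zero exactly, so any subset sum has zero
    permutation expectation.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    n = len(t)
    order = np.argsort(t, kind="mergesort")
    ts, es = t[order], e[order]
    uniq, first = np.unique(ts, return_index=True)
    # events and at-risk count per distinct time
    d = np.zeros(len(uniq))
    for i, tt in enumerate(uniq):
        d[i] = es[(ts == tt)].sum()
    n_at_risk = n - first
    cumhaz = np.cumsum(d / n_at_risk)
    haz_at = dict(zip(uniq, cumhaz))
    return e - np.array([haz_at[v] for v in t])


@dataclass
class MaxstatResult:
    cutpoint: float
    statistic: float  # max standardized |log-rank statistic|
    p_value: float
    n_candidates: int


def _lau92(b: float, low: float, high: float) -> float:
    """Improved-Bonferroni approximation for the maximally selected
    standardized statistic over the quantile band [low, high]."""
    if b <= 0:
        return 1.0
    phi = stats.norm.pdf(b)
    span = math.log(high * (1.0 - low) / (low * (1.0 - high)))
    p = 4.0 * phi / b + phi * (b - 1.0 / b) * span
    return min(1.0, max(p, 0.0))


def _maxstat_scan(x_sorted, prefix, cand_m, var_unit):
    """Standardized statistic at each candidate split (low = first m)."""
    n = len(x_sorted)
    m = cand_m.astype(float)
    var = m * (n - m) / (n * (n - 1.0)) * var_unit
    return prefix[cand_m - 1] / np.sqrt(var)


def maxstat_cutpoint(
    expression,
    time,
    event,
    quantile_bounds: tuple[float, float] = (0.10, 0.90),
    pmethod: str = "lau92",
    n_permutations: int = 10000,
    seed: int = 0,
    _scores: np.ndarray | None = None,
) -> MaxstatResult:
    """Maximally selected rank statistic for a survival dichotomy.

    Scans every observed expression value whose induced low-group
    proportion lies inside ``quantile_bounds``, standardizes the log-rank
    score sum of the low group, and returns the cutpoint with the maximal
    absolute statistic.  ``p_value`` adjusts for the maximal selection and
    is never smaller than the naive two-sided normal p at the chosen
    cutpoint.  Samples with expression equal to the cutpoint fall in the
    *low* group.
    """
    x = np.asarray(expression, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() < 1:
        raise DegenerateInputError("maxstat needs at least one event")
    q1, q2 = quantile_bounds
    if not (0.0 < q1 < q2 < 1.0):
        raise ParameterError(f"quantile_bounds must satisfy 0 < q1 < q2 < 1, got {quantile_bounds}")
    a = logrank_scores(time, event) if _scores is None else _scores
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    prefix = np.cumsum(a[order])
    var_unit = float(np.sum(a * a))
    if var_unit <= 0:
        raise DegenerateInputError("all log-rank scores are zero")
    # split after position m-1 is a candidate iff xs[m-1] < xs[m]
    boundaries = np.nonzero(np.diff(xs) > 0)[0] + 1  # possible m values
    if boundaries.size == 0:
        raise NoValidCutpointError("expression vector is constant: no cutpoint exists")
    props = boundaries / n
    cand_m = boundaries[(props >= q1) & (props <= q2)]
    if cand_m.size == 0:
        raise NoValidCutpointError(
            f"no distinct expression value inside the quantile band {quantile_bounds}"
        )
    T = _maxstat_scan(xs, prefix, cand_m, var_unit)
    absT = np.abs(T)
    b = float(absT.max())
    best = int(np.nonzero(absT >= b - 1e-12)[0][0])  # ties -> smallest cut value
    cut = float(xs[cand_m[best] - 1])

    naive = 2.0 * float(stats.norm.sf(b))
    if pmethod == "lau92":
        p = max(_lau92(b, q1, q2), naive)
    elif pmethod == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            pref = np.cumsum(rng.permutation(a))
            tp = np.abs(_maxstat_scan(xs, pref, cand_m, var_unit)).max()
            if tp >= b - 1e-12:
                hits += 1
        # selection over cutpoints can only inflate the tail probability,
        # so the naive p at the chosen cutpoint is a lower bound
        p = max((hits + 1.0) / (n_permutations + 1.0), naive)
    else:
        raise ParameterError(f"unknown pmethod {pmethod!r}")
    return MaxstatResult(cutpoint=cut, statistic=b, p_value=min(p, 1.0), n_candidates=int(cand_m.size))


# ---------------------------------------------------------------------------
# univariate Cox regression
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    coefficient: float
    hazard_ratio: float
    se: float
    z: float
    wald_p: float
    converged: bool
    warning: str | None = None


def _cox_ll_grad_hess(beta, xv, starts, death_groups, ties_method):
    w = np.exp(beta * xv)
    wx = w * xv
    wx2 = wx * xv
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1])[::-1]
    cwx2 = np.cumsum(wx2[::-1])[::-1]
    ll = 0.0
    g = 0.0
    h = 0.0
    for st, didx in zip(starts, death_groups):
        d = len(didx)
        sr, srx, srx2 = cw[st], cwx[st], cwx2[st]
        xsum = xv[didx].sum()
        if d == 1 or ties_method == "breslow":
            ll += beta * xsum - d * math.log(sr)
            mu = srx / sr
            g += xsum - d * mu
            h += d * (srx2 / sr - mu * mu)
        else:  # Efron
            sd = w[didx].sum()
            sdx = wx[didx].sum()
            sdx2 = wx2[didx].sum()
            frac = np.arange(d) / d
            den = sr - frac * sd
            num1 = srx - frac * sdx
            num2 = srx2 - frac * sdx2
            ll += beta * xsum - float(np.log(den).sum())
            phi = num1 / den
            g += xsum - float(phi.sum())
            h += float((num2 / den - phi * phi).sum())
    return ll, g, h


def cox_univariate(
    expression,
    time,
    event,
    ties_method: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-10,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton–Raphson.

    Maximizes the partial likelihood (Efron tie correction by default) for
    a single covariate; the hazard ratio is per unit of the covariate on
    its original scale and the Wald p comes from the asymptotic normal
    statistic.  Monotone-likelihood separation is detected and flagged in
    ``warning`` instead of failing silently.
    """
    x = np.asarray(expression, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.unique(x).size < 2:
        raise DegenerateInputError("Cox covariate is constant")
    if e.sum() < 2:
        raise DegenerateInputError("Cox regression needs at least two events")
    if ties_method not in ("efron", "breslow"):
        raise ParameterError(f"unknown ties_method {ties_method!r}")

    sd = float(x.std())
    xn = (x - x.mean()) / sd
    order = np.argsort(t, kind="mergesort")
    ts, es, xv = t[order], e[order], xn[order]
    ev_times = np.unique(ts[es == 1])
    starts = np.searchsorted(ts, ev_times, side="left")
    death_groups = [np.nonzero((ts == tt) & (es == 1))[0] for tt in ev_times]

    beta = 0.0
    warning = None
    converged = False
    ll, g, h = _cox_ll_grad_hess(beta, xv, starts, death_groups, ties_method)
    for _ in range(max_iter):
        if h <= 0:
            warning = "non-positive information; estimate unreliable"
            break
        step = g / h
        step = float(np.clip(step, -5.0, 5.0))
        nb = beta + step
        nll, ng, nh = _cox_ll_grad_hess(nb, xv, starts, death_groups, ties_method)
        halves = 0
        while nll < ll - 1e-12 and halves < 25:
            step *= 0.5
            nb = beta + step
            nll, ng, nh = _cox_ll_grad_hess(nb, xv, starts, death_groups, ties_method)
            halves += 1
        beta, ll, g, h = nb, nll, ng, nh
        if abs(beta) > 15.0:
            warning = (
                "monotone partial likelihood (separation): coefficient diverges, "
                "reported value is the point where iteration stopped"
            )
            break
        if abs(step) < tol or abs(g) < 1e-9:
            converged = True
            break

    if h > 0:
        se_std = 1.0 / math.sqrt(h)
        z = beta / se_std
    else:  # pragma: no cover - pathological
        se_std = float("inf")
        z = 0.0
    coef = beta / sd
    se = se_std / sd
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return CoxResult(
        coefficient=coef,
        hazard_ratio=math.exp(coef),
        se=se,
        z=z,
        wald_p=p,
        converged=converged,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# the consensus screen
# ---------------------------------------------------------------------------

_SCREEN_COLUMNS = [
    "cutpoint",
    "maxstat_statistic",
    "p_maxstat",
    "coefficient",
    "hazard_ratio",
    "p_cox",
    "logrank_chi2",
    "p_logrank",
    "direction",
    "selected",
    "n_used",
    "warning",
]


def _align_survival(matrix: pd.DataFrame, survival: pd.DataFrame):
    missing = [s for s in matrix.columns if s not in survival.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} matrix sample(s) missing from the survival table: "
            + ", ".join(map(str, missing[:10])),
            missing=missing,
        )
    sub = survival.loc[matrix.columns]
    return sub["time_months"].to_numpy(float), sub["event"].to_numpy(int)


def usat_screen(
    matrix: pd.DataFrame,
    survival: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the three-test consensus screen on every gene.

    Parameters
    ----------
    matrix
        Gene × sample expression DataFrame (log scale).
    survival
        DataFrame indexed by sample id with ``time_months`` and ``event``
        columns; must cover every matrix sample.
    config
        :class:`ScreenConfig`; defaults reproduce the original procedure.

    Returns a DataFrame with one row per gene (cutpoint, the three
    p-values, hazard ratio, direction, selected flag).  Genes that are
    degenerate (constant, or constant inside the quantile band) get NaN
    statistics and ``selected=False``.
    """
    if config is None:
        config = ScreenConfig()
    if matrix.shape[0] < 1:
        raise ParameterError("expression matrix has no genes")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique()
        raise ParameterError(f"duplicate gene ids: {list(dupes[:5])}")
    time, event = _align_survival(matrix, survival)

    full_scores = logrank_scores(time, event)
    rows = []
    values = matrix.to_numpy(float)
    for gi, gene in enumerate(matrix.index):
        x = values[gi]
        mask = np.isfinite(x)
        row = dict.fromkeys(_SCREEN_COLUMNS, np.nan)
        row["warning"] = None
        row["selected"] = False
        row["direction"] = None
        row["n_used"] = int(mask.sum())
        xm, tm, em = x[mask], time[mask], event[mask]
        scores = full_scores if mask.all() else None
        try:
            ms = maxstat_cutpoint(
                xm,
                tm,
                em,
                quantile_bounds=config.quantile_bounds,
                pmethod=config.maxstat_pmethod,
                n_permutations=config.n_permutations,
                seed=config.permutation_seed,
                _scores=scores,
            )
            low = xm <= ms.cutpoint
            chi2, p_lr = logrank_test(low.astype(int), tm, em)
            cov = xm if config.cox_covariate == "continuous" else (~low).astype(float)
            cox = cox_univariate(cov, tm, em, ties_method=config.ties_method)
        except DegenerateInputError as err:
            row["warning"] = str(err)
            rows.append(row)
            continue
        row.update(
            cutpoint=ms.cutpoint,
            maxstat_statistic=ms.statistic,
            p_maxstat=ms.p_value,
            coefficient=cox.coefficient,
            hazard_ratio=cox.hazard_ratio,
            p_cox=cox.wald_p,
            logrank_chi2=chi2,
            p_logrank=p_lr,
            direction="up_in_bad" if cox.hazard_ratio > 1.0 else "down_in_bad",
            warning=cox.warning,
        )
        rows.append(row)

    out = pd.DataFrame(rows, index=matrix.index.copy())
    out.index.name = "gene_id"

    pcols = ["p_maxstat", "p_cox", "p_logrank"]
    if config.bh_correction:
        crit = {}
        for c in pcols:
            p = out[c].to_numpy(float)
            ok = np.isfinite(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = stats.false_discovery_control(p[ok], method="bh")
            crit[c] = adj
        sel = np.all([crit[c] < config.alpha for c in pcols], axis=0)
    else:
        sel = np.all([out[c].to_numpy(float) < config.alpha for c in pcols], axis=0)
    out["selected"] = sel & out[pcols].notna().all(axis=1).to_numpy()
    return out


# ---------------------------------------------------------------------------
# gene-list overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapTable:
    """Pairwise and total overlap of named gene lists."""

    pairwise: pd.DataFrame  # symmetric intersection counts; diagonal = list size
    total_intersection: int
    union_size: int
    common_genes: tuple[str, ...]


def gene_list_overlap(named_gene_lists: Mapping[str, Iterable[str]]) -> OverlapTable:
    """Intersection structure of two or more named gene lists.

    The diagonal of ``pairwise`` holds each list's size; off-diagonal cells
    the pairwise intersection counts.  Empty lists are allowed (all their
    overlaps are 0).
    """
    names = list(named_gene_lists)
    if len(names) < 2:
        raise ParameterError("need at least two gene lists")
    sets = {k: set(v) for k, v in named_gene_lists.items()}
    pairwise = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
        dtype=int,
    )
    common = set.intersection(*sets.values()) if sets else set()
    union = set.union(*sets.values()) if sets else set()
    return OverlapTable(
        pairwise=pairwise,
        total_intersection=len(common),
        union_size=len(union),
        common_genes=tuple(sorted(common)),
    )
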