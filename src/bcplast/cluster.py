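"""Prognostic clustering on a gene signature and survival comparison.

Samples are clustered on the signature genes (Euclidean distance,
complete linkage, tree cut at k = 2 by default — named α and β), the two
clusters' Kaplan–Meier curves are compared by log-rank, and prognosis
labels (good/bad) are assigned from the survival curves rather than from
the arbitrary cluster numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    MissingGenesError,
    ParameterError,
)
from .screen import logrank_test

__all__ = [
    "ClusterAssignment",
    "KMEstimate",
    "ClusterSurvivalComparison",
    "hierarchical_cluster",
    "km_estimate",
    "survival_at",
    "compare_cluster_survival",
    "covariate_screen",
]

_GREEK = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


@dataclass
class ClusterAssignment:
    assignments: pd.Series  # sample_id -> cluster label
    leaf_order: list[str]  # dendrogram leaf order of samples
    k: int

    @property
    def clusters(self) -> list[str]:
        return sorted(self.assignments.unique())


def hierarchical_cluster(
    matrix: pd.DataFrame,
    signature_genes,
    k: int = 2,
    scaling: str = "median_center",
) -> ClusterAssignment:
    """Agglomerative clustering of samples on the signature genes.

    Euclidean distance with complete linkage, tree cut into ``k`` groups.
    ``scaling`` preprocesses each gene across the cohort: ``median_center``
    (default, the red/green heatmap convention), ``zscore`` or ``none``.
    Cluster labels for k ≤ 6 follow the Greek convention (α first in
    dendrogram leaf order).
    """
    signature_genes = list(signature_genes)
    missing = [g for g in signature_genes if g not in matrix.index]
    if missing:
        raise MissingGenesError(missing)
    if matrix.shape[1] < k:
        raise ParameterError(f"need at least k={k} samples, got {matrix.shape[1]}")

    sub = matrix.loc[signature_genes].astype(float)
    if scaling == "median_center":
        sub = sub.sub(sub.median(axis=1), axis=0)
    elif scaling == "zscore":
        sub = sub.sub(sub.mean(axis=1), axis=0)
        sd = sub.std(axis=1).replace(0.0, 1.0)
        sub = sub.div(sd, axis=0)
    elif scaling != "none":
        raise ParameterError(f"unknown scaling {scaling!r}")

    X = sub.T.to_numpy()
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, k, criterion="maxclust")
    samples = list(sub.columns)
    leaf_order = [samples[i] for i in leaves_list(Z)]
    # name clusters deterministically by first appearance in leaf order
    seen: dict[int, str] = {}
    order_of = {s: i for i, s in enumerate(samples)}
    for s in leaf_order:
        c = raw[order_of[s]]
        if c not in seen:
            name = _GREEK[len(seen)] if len(seen) < len(_GREEK) else f"c{len(seen) + 1}"
            seen[c] = name
    labels = pd.Series(
        [seen[c] for c in raw], index=pd.Index(samples, name="sample_id"), name="cluster"
    )
    return ClusterAssignment(assignments=labels, leaf_order=leaf_order, k=k)


@dataclass
class KMEstimate:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival_probabilities: np.ndarray
    n_at_risk: np.ndarray
    median_survival: float | None  # None if the curve never crosses 0.5
    n_samples: int
    n_events: int


def km_estimate(time, event) -> KMEstimate:
    """Kaplan–Meier estimate of one group's survival."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(t) < 1:
        raise DegenerateInputError("empty survival subset")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    table = kmf.event_table
    med = kmf.median_survival_time_
    return KMEstimate(
        times=sf.index.to_numpy(float),
        survival_probabilities=sf.iloc[:, 0].to_numpy(float),
        n_at_risk=table["at_risk"].to_numpy(int),
        median_survival=None if np.isinf(med) else float(med),
        n_samples=len(t),
        n_events=int(e.sum()),
    )


def survival_at(km: KMEstimate, t: float) -> float:
    """Step-function evaluation of the KM curve at time t."""
    idx = np.searchsorted(km.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(km.survival_probabilities[idx])


@dataclass
class ClusterSurvivalComparison:
    km_by_cluster: dict[str, KMEstimate]
    logrank_chi2: float
    logrank_p: float
    prognosis: dict[str, str]  # cluster label -> "good" / "bad"
    medians: dict[str, float | None]


def compare_cluster_survival(
    assignment: ClusterAssignment,
    survival: pd.DataFrame,
    tie_horizon_months: float = 24.0,
) -> ClusterSurvivalComparison:
    """Compare the two clusters' survival and label prognosis.

    The cluster with the lower Kaplan–Meier curve is labelled *bad*:
    primarily by median survival (an unreached median counts as infinite),
    with ties broken by the survival probability at ``tie_horizon_months``
    and finally by size (the larger cluster is labelled good).  The
    log-rank p reuses :func:`bcplast.screen.logrank_test` on the same
    partition.
    """
    labels = assignment.assignments
    if assignment.k != 2 or len(set(labels)) != 2:
        raise ParameterError("prognosis comparison is defined for exactly two clusters")
    missing = [s for s in labels.index if s not in survival.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} clustered sample(s) have no survival record", missing=missing
        )
    surv = survival.loc[labels.index]
    t = surv["time_months"].to_numpy(float)
    e = surv["event"].to_numpy(int)

    kms: dict[str, KMEstimate] = {}
    for c in sorted(labels.unique()):
        m = (labels == c).to_numpy()
        kms[c] = km_estimate(t[m], e[m])
    chi2, p = logrank_test(labels.to_numpy(), t, e)

    def sort_key(c):
        med = kms[c].median_survival
        return (
            med if med is not None else np.inf,
            survival_at(kms[c], tie_horizon_months),
            kms[c].n_samples,
        )

    c1, c2 = sorted(kms, key=sort_key)
    prognosis = {c1: "bad", c2: "good"}
    return ClusterSurvivalComparison(
        km_by_cluster=kms,
        logrank_chi2=chi2,
        logrank_p=p,
        prognosis=prognosis,
        medians={c: kms[c].median_survival for c in kms},
    )


def covariate_screen(
    clinical: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Univariate log-rank screen of categorical clinical covariates.

    Each covariate's observed levels define the groups of a log-rank test;
    samples with a missing value are excluded (count reported).
    Covariates with fewer than two observed levels are skipped with a
    warning and reported with NaN statistics.
    """
    if covariates is None:
        covariates = [c for c in clinical.columns if c not in ("time_months", "event")]
    rows = []
    for cov in covariates:
        s = clinical[cov]
        mask = s.notna()
        n_missing = int((~mask).sum())
        levels = s[mask].unique()
        if len(levels) < 2:
            warnings.warn(f"covariate {cov!r} has fewer than two observed levels; skipped")
            rows.append(
                {"covariate": cov, "n_levels": len(levels), "n_used": int(mask.sum()),
                 "n_missing": n_missing, "chi2": np.nan, "p_value": np.nan}
            )
            continue
        chi2, p = logrank_test(
            s[mask].to_numpy(),
            clinical.loc[mask, "time_months"].to_numpy(float),
            clinical.loc[mask, "event"].to_numpy(int),
        )
        rows.append(
            {"covariate": cov, "n_levels": len(levels), "n_used": int(mask.sum()),
             "n_missing": n_missing, "chi2": chi2, "p_value": p}
        )
    return (
        pd.DataFrame(rows)
        .set_index("covariate")
        .sort_values("p_value", na_position="last")
    )
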