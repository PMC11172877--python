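"""Synthetic cohorts with known ground truth.

Four generators cover the inputs of the downstream stages:

* :func:`simulate_survival_cohort` — a microarray-like log-expression
  cohort with two latent prognostic groups, planted survival-associated
  genes, exponential survival with a proportional-hazards group effect,
  and independent uniform right-censoring;
* :func:`simulate_paired_shift` — matched pre/post-treatment pairs with a
  controlled epithelial→mesenchymal shift of the Delta(r) score;
* :func:`simulate_subtyped_cohort` — paired subtype-structured cohorts
  drawn around centroids with a known class-switch matrix;
* :func:`simulate_count_matrix` — negative-binomial RNA-seq counts with
  known per-sample size factors and gene lengths.

All randomness flows from the explicit ``seed`` argument; identical seeds
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import ParameterError
from .stemness import StemnessTemplates

__all__ = [
    "SurvivalCohortTruth",
    "PairedShiftTruth",
    "SubtypeCohortTruth",
    "CountTruth",
    "PairedCohort",
    "simulate_survival_cohort",
    "simulate_paired_shift",
    "simulate_subtyped_cohort",
    "simulate_count_matrix",
    "synthetic_templates",
    "synthetic_centroids",
]


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCohortTruth:
    latent_group: pd.Series  # 0 = good prognosis, 1 = bad prognosis
    planted_genes: pd.DataFrame  # index gene_id, column "direction" (+1 up in bad)
    hazard_ratio_between_groups: float
    censoring_fraction: float
    baseline_hazard: float
    effect_size: float


def _censoring_horizon(hazards: np.ndarray, fraction: float) -> float:
    """Horizon c of U(0, c) censoring giving the target censored fraction
    in expectation, for exponential survival with the given hazards."""

    def expected_censored(c):
        lc = hazards * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc)) - fraction

    return optimize.brentq(expected_censored, 1e-9, 1e9)


def simulate_survival_cohort(
    n_samples: int = 100,
    n_genes: int = 2000,
    n_planted: int = 20,
    hazard_ratio: float = 4.0,
    censoring_fraction: float = 0.3,
    seed: int = 0,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    baseline_hazard: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, SurvivalCohortTruth]:
    """Two-group prognostic cohort with planted survival-associated genes.

    Samples split evenly into a good-prognosis group (exponential hazard
    ``baseline_hazard`` per month) and a bad-prognosis group (hazard
    multiplied by ``hazard_ratio``).  Expression is Gaussian on a log2
    scale; planted genes are shifted by ``effect_size`` between the
    groups, alternating up/down in the bad group.  Censoring is
    independent uniform on an interval solved to hit
    ``censoring_fraction`` in expectation.

    Returns ``(matrix, survival, truth)``: a genes × samples DataFrame, a
    clinical table indexed by sample id with ``time_months``/``event``
    columns, and the ground truth.
    """
    if n_samples < 8:
        raise ParameterError("n_samples must be at least 8")
    if n_genes < 1 or n_planted < 0:
        raise ParameterError("non-positive dimensions")
    if n_planted > n_genes:
        raise ParameterError("n_planted cannot exceed n_genes")
    if hazard_ratio <= 0:
        raise ParameterError("hazard_ratio must be positive")
    if baseline_hazard <= 0:
        raise ParameterError("baseline_hazard must be positive")
    if not (0.0 <= censoring_fraction < 1.0):
        raise ParameterError("censoring_fraction must be in [0, 1)")
    if noise_sd < 0 or effect_size < 0:
        raise ParameterError("noise_sd and effect_size must be non-negative")

    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]

    group = np.zeros(n_samples, dtype=int)
    group[: n_samples // 2] = 1
    rng.shuffle(group)

    base = rng.normal(7.0, 2.0, size=n_genes)
    expr = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    planted_idx = np.sort(rng.choice(n_genes, size=n_planted, replace=False))
    directions = np.where(np.arange(n_planted) % 2 == 0, 1, -1)
    for gi, sign in zip(planted_idx, directions):
        expr[gi, group == 1] += sign * effect_size

    hazards = baseline_hazard * hazard_ratio**group
    t_true = rng.exponential(1.0 / hazards)
    if censoring_fraction == 0.0:
        time = t_true
        event = np.ones(n_samples, dtype=int)
    else:
        horizon = _censoring_horizon(hazards, censoring_fraction)
        c = rng.uniform(0.0, horizon, size=n_samples)
        time = np.minimum(t_true, c)
        event = (t_true <= c).astype(int)
    time = np.maximum(time, 1e-6)

    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    survival = pd.DataFrame(
        {"time_months": time, "event": event},
        index=pd.Index(samples, name="sample_id"),
    )
    truth = SurvivalCohortTruth(
        latent_group=pd.Series(group, index=survival.index, name="latent_group"),
        planted_genes=pd.DataFrame(
            {"direction": directions},
            index=pd.Index([genes[i] for i in planted_idx], name="gene_id"),
        ),
        hazard_ratio_between_groups=float(hazard_ratio),
        censoring_fraction=float(censoring_fraction),
        baseline_hazard=float(baseline_hazard),
        effect_size=float(effect_size),
    )
    return matrix, survival, truth


# ---------------------------------------------------------------------------
# paired epithelial -> mesenchymal shift
# ---------------------------------------------------------------------------


def synthetic_templates(n_genes: int = 15, seed: int = 7) -> StemnessTemplates:
    """Synthetic stand-in for the published stem/non-stem signature.

    15 genes with a standardized Gaussian NS/E profile and the exactly
    anti-correlated CS/M profile, so a sample equal to one pole scores
    Delta(r) = ±2.  The real template values are an input file in
    production use; this object only mirrors their shape.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=n_genes)
    v = (v - v.mean()) / v.std()
    idx = pd.Index([f"sig{i + 1:02d}" for i in range(n_genes)], name="gene_id")
    nse = pd.Series(v, index=idx, name="NS_E")
    return StemnessTemplates(nse=nse, csm=-nse.rename("CS_M"))


@dataclass
class PairedShiftTruth:
    pair_map: dict[str, str]  # pre sample id -> post sample id
    shift_magnitude: float
    template_set: StemnessTemplates
    delta_pre: pd.Series
    delta_post: pd.Series


def _orthonormal_noise(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """Unit-sd centered vector orthogonal to the (centered, unit-sd) u."""
    n = len(u)
    while True:
        z = rng.normal(size=n)
        z = z - z.mean()
        z = z - (z @ u) / (u @ u) * u
        sd = z.std()
        if sd > 1e-8:
            return z / sd


def simulate_paired_shift(
    n_pairs: int = 50,
    shift_magnitude: float = 0.25,
    noise_sd: float = 0.05,
    seed: int = 0,
    templates: StemnessTemplates | None = None,
    baseline_delta_mean: float = -0.3,
    baseline_delta_sd: float = 0.2,
) -> tuple[pd.DataFrame, PairedShiftTruth]:
    """Matched pre/post pairs with a controlled mean Delta(r) shift.

    With anti-correlated poles, Delta(r) = −2·r(sample, NS/E); each pre
    sample is built with an exact target correlation to the NS/E profile
    and its post partner with the correlation giving Delta(r) increased by
    ``shift_magnitude``.  At ``noise_sd = 0`` the recovered paired mean
    difference equals ``shift_magnitude`` to numerical precision; small
    noise only attenuates it within Monte-Carlo error.
    """
    if n_pairs < 2:
        raise ParameterError("n_pairs must be at least 2")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    if not (-2.0 <= shift_magnitude <= 2.0):
        raise ParameterError("shift_magnitude must lie in [-2, 2] (a difference of correlations)")

    rng = np.random.default_rng(seed)
    if templates is None:
        templates = synthetic_templates(seed=int(rng.integers(0, 2**31 - 1)))
    u = templates.nse.iloc[:, 0].to_numpy(float)
    u = (u - u.mean()) / u.std()
    genes = templates.gene_list

    lo = max(-1.95, -1.95 - shift_magnitude)
    hi = min(1.95, 1.95 - shift_magnitude)
    delta_pre = np.clip(
        rng.normal(baseline_delta_mean, baseline_delta_sd, size=n_pairs), lo, hi
    )
    delta_post = delta_pre + shift_magnitude

    cols = {}
    for i in range(n_pairs):
        for tag, dlt in (("pre", delta_pre[i]), ("post", delta_post[i])):
            r = -dlt / 2.0  # correlation with the NS/E pole
            z = _orthonormal_noise(rng, u)
            vec = r * u + np.sqrt(max(0.0, 1.0 - r * r)) * z
            vec = 8.0 + vec + noise_sd * rng.normal(size=len(u))
            cols[f"{tag}_{i + 1:03d}"] = vec
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    pair_map = {f"pre_{i + 1:03d}": f"post_{i + 1:03d}" for i in range(n_pairs)}
    truth = PairedShiftTruth(
        pair_map=pair_map,
        shift_magnitude=float(shift_magnitude),
        template_set=templates,
        delta_pre=pd.Series(delta_pre, index=list(pair_map)),
        delta_post=pd.Series(delta_post, index=list(pair_map.values())),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# subtype-structured paired cohort
# ---------------------------------------------------------------------------


def synthetic_centroids(
    n_genes: int = 50,
    class_names: Sequence[str] = ("Basal", "HER2", "LumA", "LumB", "Normal"),
    seed: int = 11,
) -> pd.DataFrame:
    """Random near-orthogonal centroid profiles (genes × classes)."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"cg{i + 1:03d}" for i in range(n_genes)], name="gene_id")
    return pd.DataFrame(
        rng.normal(size=(n_genes, len(class_names))), index=idx, columns=list(class_names)
    )


class PairedCohort(NamedTuple):
    pre: pd.DataFrame
    post: pd.DataFrame
    pairs: pd.DataFrame  # columns sample_pre, sample_post


@dataclass
class SubtypeCohortTruth:
    true_labels_pre: pd.Series
    true_labels_post: pd.Series
    switch_matrix: pd.DataFrame  # row-stochastic, rows = pre class
    centroids: pd.DataFrame


def simulate_subtyped_cohort(
    n_per_class: int = 20,
    centroids: pd.DataFrame | None = None,
    switch_matrix: pd.DataFrame | np.ndarray | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[PairedCohort, SubtypeCohortTruth]:
    """Paired cohort drawn around centroids with a known class-switch law.

    Timepoint-1 samples are drawn around their class centroid
    (``n_per_class`` per class, isotropic Gaussian noise); each timepoint-2
    class is drawn from the corresponding row of ``switch_matrix`` (the
    identity by default) and its expression around the new centroid.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if centroids is None:
        centroids = synthetic_centroids(seed=int(rng.integers(0, 2**31 - 1)))
    classes = list(centroids.columns)
    k = len(classes)
    if k < 2:
        raise ParameterError("centroids must define at least two classes")
    if switch_matrix is None:
        sw = np.eye(k)
    else:
        sw = (
            switch_matrix.loc[classes, classes].to_numpy(float)
            if isinstance(switch_matrix, pd.DataFrame)
            else np.asarray(switch_matrix, dtype=float)
        )
    if sw.shape != (k, k) or (sw < 0).any() or not np.allclose(sw.sum(axis=1), 1.0, atol=1e-9):
        raise ParameterError("switch_matrix must be a K x K row-stochastic matrix")

    prof = centroids.to_numpy(float)
    pre_cols, post_cols = {}, {}
    labels_pre, labels_post, pre_ids, post_ids = [], [], [], []
    i = 0
    for ci, cls in enumerate(classes):
        for _ in range(n_per_class):
            i += 1
            pid = f"p{i:03d}"
            c2 = int(rng.choice(k, p=sw[ci]))
            pre_cols[f"{pid}_t1"] = prof[:, ci] + rng.normal(0.0, noise_sd, size=prof.shape[0])
            post_cols[f"{pid}_t2"] = prof[:, c2] + rng.normal(0.0, noise_sd, size=prof.shape[0])
            pre_ids.append(f"{pid}_t1")
            post_ids.append(f"{pid}_t2")
            labels_pre.append(cls)
            labels_post.append(classes[c2])

    pre = pd.DataFrame(pre_cols, index=centroids.index.copy())
    post = pd.DataFrame(post_cols, index=centroids.index.copy())
    pairs = pd.DataFrame({"sample_pre": pre_ids, "sample_post": post_ids})
    truth = SubtypeCohortTruth(
        true_labels_pre=pd.Series(labels_pre, index=pre_ids, name="label"),
        true_labels_post=pd.Series(labels_post, index=post_ids, name="label"),
        switch_matrix=pd.DataFrame(sw, index=classes, columns=classes),
        centroids=centroids,
    )
    return PairedCohort(pre=pre, post=post, pairs=pairs), truth


# ---------------------------------------------------------------------------
# negative-binomial count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountTruth:
    true_size_factors: pd.Series
    gene_lengths: pd.Series
    dispersion: float
    base_means: pd.Series


def simulate_count_matrix(
    n_genes: int = 1000,
    n_samples: int = 6,
    true_size_factors: Sequence[float] | None = None,
    gene_lengths: Sequence[int] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    mean_log: float = 4.0,
    mean_log_sd: float = 1.5,
) -> tuple[pd.DataFrame, CountTruth]:
    """Negative-binomial counts with known size factors and gene lengths.

    Gene base means are log-normal; sample j's expected count for gene g
    is ``size_factor_j * mean_g``; counts are gamma–Poisson with
    ``Var = mu + dispersion * mu^2`` (Poisson at dispersion 0).
    """
    if n_genes < 1 or n_samples < 1:
        raise ParameterError("non-positive dimensions")
    if dispersion < 0:
        raise ParameterError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    if true_size_factors is None:
        sf = rng.lognormal(0.0, 0.3, size=n_samples)
        sf = sf / np.exp(np.mean(np.log(sf)))
    else:
        sf = np.asarray(true_size_factors, dtype=float)
        if len(sf) != n_samples or (sf <= 0).any():
            raise ParameterError("size factors must be positive, one per sample")
    if gene_lengths is None:
        lengths = rng.integers(300, 10000, size=n_genes)
    else:
        lengths = np.asarray(gene_lengths, dtype=int)
        if len(lengths) != n_genes or (lengths < 1).any():
            raise ParameterError("gene lengths must be >= 1, one per gene")

    base = rng.lognormal(mean_log, mean_log_sd, size=n_genes)
    mu = base[:, None] * sf[None, :]
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)

    genes = pd.Index([f"g{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    samples = [f"s{j + 1:02d}" for j in range(n_samples)]
    matrix = pd.DataFrame(counts.astype(int), index=genes, columns=samples)
    truth = CountTruth(
        true_size_factors=pd.Series(sf, index=samples, name="size_factor"),
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
        dispersion=float(dispersion),
        base_means=pd.Series(base, index=genes, name="base_mean"),
    )
    return matrix, truth
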