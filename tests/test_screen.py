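"""Unit and oracle tests for the consensus survival screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bcplast.exceptions import (
    AlignmentError,
    DegenerateInputError,
    NoValidCutpointError,
    ParameterError,
)
from bcplast.simulate import simulate_survival_cohort
from bcplast.screen import (
    OverlapTable,
    ScreenConfig,
    cox_univariate,
    gene_list_overlap,
    logrank_scores,
    logrank_test,
    maxstat_cutpoint,
    usat_screen,
)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [2.0, 5.0, 8.0, 2.0, 5.0, 8.0]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_event_times_match_hand_computed_tables(self):
        # group 1 events at t=1,2,3; group 2 at t=4,5,6; no censoring.
        # Summing O-E and hypergeometric variances over the six 2x2 tables
        # by hand: O1=3, E1=1/2+2/5+1/4, V=1/4+6/25+3/16 -> chi2=1.85^2/V.
        e1 = 3 - (0.5 + 0.4 + 0.25)
        v = 0.25 + 6 / 25 + 3 / 16
        chi2, p = logrank_test([1, 1, 1, 2, 2, 2], [1, 2, 3, 4, 5, 6], [1] * 6)
        assert chi2 == pytest.approx(e1**2 / v, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(e1**2 / v, 1), rel=1e-12)

    def test_agrees_with_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.7).astype(int)
        g = rng.integers(0, 2, 30)
        chi2, p = logrank_test(g, t, e)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_p_value_matches_label_permutation_null(self):
        rng = np.random.default_rng(7)
        n = 20
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.8).astype(int)
        g = rng.integers(0, 2, n)
        chi2, p = logrank_test(g, t, e)
        reps = 4000
        hits = 0
        for _ in range(reps):
            cp, _ = logrank_test(rng.permutation(g), t, e)
            if cp >= chi2 - 1e-12:
                hits += 1
        p_perm = hits / reps
        assert p == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / reps) + 0.02)

    def test_invariant_to_monotone_group_relabeling(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 25)
        e = (rng.random(25) < 0.7).astype(int)
        g = rng.integers(0, 3, 25)
        chi2a, pa = logrank_test(g, t, e)
        relabeled = np.array(["aa", "bb", "cc"])[g]
        chi2b, pb = logrank_test(relabeled, t, e)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)
        assert pa == pytest.approx(pb, rel=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            logrank_test([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])  # single group
        with pytest.raises(DegenerateInputError):
            logrank_test([0, 0, 1, 1], [1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])  # no events


# ---------------------------------------------------------------------------
# maxstat
# ---------------------------------------------------------------------------


def _oracle_max_split(x, scores, q1, q2):
    """Independent exhaustive-scan oracle: standardized score sum of every
    admissible low group, computed subset by subset."""
    n = len(x)
    ss = float(np.sum(scores**2))
    best = (None, -1.0)
    for cut in np.unique(x)[:-1]:
        low = x <= cut
        m = int(low.sum())
        if not (q1 <= m / n <= q2):
            continue
        s = scores[low].sum()
        t = abs(s) / np.sqrt(m * (n - m) / (n * (n - 1)) * ss)
        if t > best[1] + 1e-12:
            best = (float(cut), float(t))
    return best


class TestMaxstat:
    def test_perfect_separation_finds_the_separating_value(self):
        # low half: early events; high half: late, mostly censored
        n = 24
        x = np.concatenate([np.full(n // 2, 1.0), np.full(n // 2, 5.0)])
        t = np.concatenate([np.linspace(1, 6, n // 2), np.linspace(40, 60, n // 2)])
        e = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
        e[-1] = 1  # one late event keeps things non-degenerate
        res = maxstat_cutpoint(x, t, e)
        assert res.cutpoint == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_cutpoint_and_statistic_match_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 30
            x = r.normal(size=n)
            t = r.exponential(10, n)
            e = (r.random(n) < 0.7).astype(int)
            res = maxstat_cutpoint(x, t, e)
            scores = logrank_scores(t, e)
            cut, stat = _oracle_max_split(x, scores, 0.10, 0.90)
            assert res.cutpoint == pytest.approx(cut)
            assert res.statistic == pytest.approx(stat, rel=1e-9)

    def test_adjusted_p_never_below_naive_p_at_cutpoint(self):
        for seed in range(8):
            r = np.random.default_rng(seed)
            x = r.normal(size=40)
            t = r.exponential(10, 40)
            e = (r.random(40) < 0.6).astype(int)
            res = maxstat_cutpoint(x, t, e)
            naive = 2 * stats.norm.sf(res.statistic)
            assert res.p_value >= naive - 1e-12

    def test_null_type_one_error_is_controlled(self):
        # expression independent of survival: adjusted p < 0.05 in <= ~5%
        reps, hits = 400, 0
        for seed in range(reps):
            r = np.random.default_rng(10_000 + seed)
            x = r.normal(size=40)
            t = r.exponential(10, 40)
            e = (r.random(40) < 0.7).astype(int)
            if maxstat_cutpoint(x, t, e).p_value < 0.05:
                hits += 1
        # 4 sigma Monte Carlo margin above the nominal level
        assert hits / reps <= 0.05 + 4 * np.sqrt(0.05 * 0.95 / reps)

    def test_permutation_p_matches_independent_permutation_oracle(self):
        rng = np.random.default_rng(21)
        n = 20
        x = rng.normal(size=n)
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.8).astype(int)
        res = maxstat_cutpoint(x, t, e, pmethod="permutation", n_permutations=4000, seed=1)
        # oracle: explicit subset sums under independently drawn permutations
        scores = logrank_scores(t, e)
        _, observed = _oracle_max_split(x, scores, 0.10, 0.90)
        r2 = np.random.default_rng(999)
        hits = 0
        reps = 4000
        for _ in range(reps):
            _, tp = _oracle_max_split(x, r2.permutation(scores), 0.10, 0.90)
            if tp >= observed - 1e-12:
                hits += 1
        p_oracle = (hits + 1) / (reps + 1)
        mc = 4 * np.sqrt(p_oracle * (1 - p_oracle) / reps) + 0.01
        assert res.p_value == pytest.approx(p_oracle, abs=mc)

    def test_constant_vector_raises(self):
        with pytest.raises(NoValidCutpointError):
            maxstat_cutpoint(np.ones(20), np.arange(1, 21), np.ones(20, int))

    def test_all_censored_raises(self):
        with pytest.raises(DegenerateInputError):
            maxstat_cutpoint(np.arange(20.0), np.arange(1, 21), np.zeros(20, int))


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


def _partial_loglik(beta, x, t, e):
    """Explicit partial likelihood for distinct event times (no ties)."""
    ll = 0.0
    for i in np.nonzero(e)[0]:
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_coefficient_matches_grid_search_of_partial_likelihood(self):
        x = np.array([0.5, -1.0, 1.2, -0.3, 0.9, -1.8])
        t = np.array([4.0, 2.0, 9.0, 6.0, 1.0, 12.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        res = cox_univariate(x, t, e)
        grid = np.linspace(-5, 5, 200001)
        lls = [_partial_loglik(b, x, t, e) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert res.coefficient == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 50
        x = rng.normal(size=n)
        t = np.round(rng.exponential(10, n), 0) + 1  # heavy ties
        e = (rng.random(n) < 0.8).astype(int)
        res = cox_univariate(x, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "T": t, "E": e}), duration_col="T", event_col="E"
        )
        assert res.coefficient == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)
        assert res.wald_p == pytest.approx(cph.summary.loc["x", "p"], rel=1e-3)

    def test_linear_reparameterization_halves_the_coefficient(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=30)
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.8).astype(int)
        a = cox_univariate(x, t, e)
        b = cox_univariate(2 * x, t, e)
        assert b.coefficient == pytest.approx(a.coefficient / 2, rel=1e-9)
        assert b.hazard_ratio == pytest.approx(np.exp(a.coefficient / 2), rel=1e-9)
        assert b.wald_p == pytest.approx(a.wald_p, rel=1e-9)

    def test_null_covariate_gives_unit_hazard_ratio(self):
        rng = np.random.default_rng(19)
        n = 400
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.8).astype(int)
        res = cox_univariate(rng.normal(size=n), t, e)
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.25)
        assert res.converged

    def test_separation_is_flagged_not_silent(self):
        # covariate perfectly orders survival with all events: monotone likelihood
        n = 20
        x = np.arange(n, dtype=float)
        t = np.arange(1, n + 1, dtype=float)
        e = np.ones(n, int)
        res = cox_univariate(-x, t, e)
        assert res.warning is not None

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            cox_univariate(np.ones(10), np.arange(1, 11), np.ones(10, int))
        with pytest.raises(DegenerateInputError):
            cox_univariate(np.arange(10.0), np.arange(1, 11), np.zeros(10, int))


# ---------------------------------------------------------------------------
# the consensus screen
# ---------------------------------------------------------------------------


class TestUsatScreen:
    def test_selected_implies_all_three_p_below_alpha(self, survival_cohort):
        matrix, survival, _ = survival_cohort
        res = usat_screen(matrix.iloc[:80], survival)
        sel = res[res["selected"]]
        assert len(sel) > 0
        assert (sel[["p_maxstat", "p_cox", "p_logrank"]].max(axis=1) < 0.05).all()
        not_sel = res[~res["selected"] & res["p_maxstat"].notna()]
        assert (not_sel[["p_maxstat", "p_cox", "p_logrank"]].max(axis=1) >= 0.05).all()

    def test_direction_matches_hazard_ratio_sign(self, survival_cohort):
        matrix, survival, _ = survival_cohort
        res = usat_screen(matrix.iloc[:40], survival).dropna(subset=["hazard_ratio"])
        up = res["direction"] == "up_in_bad"
        assert (res.loc[up, "hazard_ratio"] > 1).all()
        assert (res.loc[~up, "hazard_ratio"] <= 1).all()

    def test_alpha_zero_selects_nothing(self, survival_cohort):
        matrix, survival, _ = survival_cohort
        res = usat_screen(matrix.iloc[:20], survival, ScreenConfig(alpha=0.0))
        assert not res["selected"].any()

    def test_planted_genes_recovered_with_high_sensitivity(self, survival_cohort):
        matrix, survival, truth = survival_cohort
        res = usat_screen(matrix, survival)
        selected = set(res.index[res["selected"]])
        sens = len(selected & set(truth.planted_genes.index)) / len(truth.planted_genes)
        assert sens >= 0.8

    def test_small_neoadjuvant_sized_cohort_yields_nonempty_signature(self):
        # a 22-sample cohort with a strong planted signature still produces
        # a non-empty consensus gene list (its size varies with the draw)
        matrix, survival, _ = simulate_survival_cohort(
            n_samples=22, n_genes=300, n_planted=20, hazard_ratio=4.0,
            censoring_fraction=0.3, seed=0,
        )
        res = usat_screen(matrix, survival)
        assert len(res) == 300
        assert res["selected"].sum() > 0

    def test_invariant_to_row_and_column_ordering(self, survival_cohort):
        matrix, survival, _ = survival_cohort
        sub = matrix.iloc[:25]
        rng = np.random.default_rng(23)
        shuffled = sub.iloc[rng.permutation(len(sub)), rng.permutation(sub.shape[1])]
        a = usat_screen(sub, survival)
        b = usat_screen(shuffled, survival).loc[a.index]
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_sample_mismatch_raises_alignment_error_listing_ids(self, survival_cohort):
        matrix, survival, _ = survival_cohort
        with pytest.raises(AlignmentError) as err:
            usat_screen(matrix.iloc[:5], survival.drop(index=[matrix.columns[3]]))
        assert matrix.columns[3] in err.value.missing

    def test_constant_gene_recorded_as_unselected_not_fatal(self, survival_cohort):
        matrix, survival, _ = survival_cohort
        m = matrix.iloc[:10].copy()
        m.iloc[0] = 3.14
        res = usat_screen(m, survival)
        assert not res.iloc[0]["selected"]
        assert np.isnan(res.iloc[0]["p_maxstat"])
        assert res.iloc[1:]["p_maxstat"].notna().all()


# ---------------------------------------------------------------------------
# gene-list overlap
# ---------------------------------------------------------------------------


class TestGeneListOverlap:
    def test_identity_disjoint_and_hand_enumerated_cases(self):
        res = gene_list_overlap({"A": ["a", "b", "c"], "B": ["a", "b", "c"]})
        assert res.pairwise.loc["A", "B"] == 3
        assert res.total_intersection == 3

        res = gene_list_overlap({"A": ["a", "b"], "B": ["c", "d"], "C": []})
        assert (res.pairwise.to_numpy() == np.diag([2, 2, 0])).all()
        assert res.total_intersection == 0

        res = gene_list_overlap({"L1": ["a", "b", "c"], "L2": ["b", "c", "d"], "L3": ["c", "e"]})
        assert res.total_intersection == 1
        assert res.common_genes == ("c",)
        assert res.pairwise.loc["L1", "L2"] == 2
        assert res.pairwise.loc["L1", "L3"] == 1
        assert res.pairwise.loc["L2", "L3"] == 1
        assert res.union_size == 5

    def test_single_list_rejected(self):
        with pytest.raises(ParameterError):
            gene_list_overlap({"A": ["a"]})
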