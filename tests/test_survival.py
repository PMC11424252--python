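"""OxPhos scoring, stratification, survival statistics and the nested
patient-level comparison, checked against hand-worked and exhaustive
oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tcatrace.cohort import generate_survival_cohort
from tcatrace.survival import (
    ExpressionMatrix,
    GeneSet,
    bh_adjust,
    km_estimate,
    logrank_test,
    nested_comparison,
    oxphos_score,
    stratify,
)


def make_matrix(values, log_scale=True):
    clinical = pd.DataFrame(index=values.columns)
    return ExpressionMatrix(values, clinical, log_scale=log_scale)


class TestOxphosScore:
    def test_rank_one_matrix_scores_proportional_to_shared_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        values = pd.DataFrame(
            [profile, 2 * profile + 1],
            index=["g1", "g2"],
            columns=[f"s{i}" for i in range(4)],
        )
        scores = oxphos_score(make_matrix(values), GeneSet("set", ["g1", "g2"]))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(np.corrcoef(scores, z)[0, 1], 1.0, atol=1e-12)

    def test_group_shift_raises_median_score(self):
        for seed in range(20):
            matrix, z = generate_survival_cohort(n=60, beta=0.0, seed=seed)
            scores = oxphos_score(
                matrix, GeneSet("oxphos", [g for g in matrix.values.index if g.startswith("OXP")])
            )
            high = z >= z.median()
            assert scores[high].median() > scores[~high].median()

    def test_sample_permutation_equivariance(self, rng):
        matrix, _ = generate_survival_cohort(n=30, seed=3)
        gene_set = GeneSet("oxphos", [g for g in matrix.values.index if g.startswith("OXP")])
        scores = oxphos_score(matrix, gene_set)
        perm = rng.permutation(matrix.values.columns)
        permuted = ExpressionMatrix(matrix.values[perm], matrix.clinical.loc[perm], log_scale=True)
        scores_p = oxphos_score(permuted, gene_set)
        np.testing.assert_allclose(scores_p[scores.index].abs(), scores.abs(), atol=1e-8)

    def test_invariant_to_absent_genes_and_gene_order(self):
        matrix, _ = generate_survival_cohort(n=30, seed=4)
        genes = [g for g in matrix.values.index if g.startswith("OXP")]
        s1 = oxphos_score(matrix, GeneSet("a", genes))
        s2 = oxphos_score(matrix, GeneSet("b", list(reversed(genes)) + ["NOT_A_GENE"]))
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_too_few_set_genes_rejected(self):
        matrix, _ = generate_survival_cohort(n=30, seed=5)
        with pytest.raises(ValueError):
            oxphos_score(matrix, GeneSet("tiny", ["OXP001"]))


class TestStratify:
    def test_median_split_hand_case(self):
        vals = pd.Series(np.arange(1, 11, dtype=float), index=[f"s{i}" for i in range(10)])
        labels = stratify(vals, "median")
        assert (labels.iloc[:5] == "low").all() and (labels.iloc[5:] == "high").all()

    def test_quantile_30_70(self):
        vals = pd.Series(np.arange(1, 11, dtype=float), index=[f"s{i}" for i in range(10)])
        labels = stratify(vals, "quantile")
        assert set(labels.index[labels == "low"]) == {"s0", "s1", "s2"}
        assert set(labels.index[labels == "high"]) == {"s7", "s8", "s9"}
        assert len(labels) == 6

    def test_grade_stage_filter_matches_manual_subset(self):
        idx = [f"s{i}" for i in range(8)]
        clinical = pd.DataFrame(
            {"grade": [1, 2, 3, 4, 3, 4, 3, 4], "stage": [3, 4, 1, 2, 3, 4, 3, 4]},
            index=idx,
        )
        vals = pd.Series(np.arange(8, dtype=float), index=idx)
        labels = stratify(vals, "median", clinical, grades=(3, 4), stages=(3, 4))
        assert set(labels.index) == {"s4", "s5", "s6", "s7"}

    def test_identical_values_rejected(self):
        vals = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError):
            stratify(vals)


class TestKaplanMeier:
    def test_single_subject(self):
        km = km_estimate([5.0], [1])
        assert km.median == 5.0
        assert km.survival[-1] == 0.0

    def test_all_censored_median_not_reached(self):
        km = km_estimate([3.0, 6.0, 9.0], [0, 0, 0])
        assert not km.median_reached
        np.testing.assert_allclose(km.survival, 1.0)

    def test_six_subject_hand_product_limit_table(self):
        """times 1..6, events (1,0,1,1,0,1): hand product-limit gives
        S = 5/6, 5/6, 5/8, 5/12, 5/12, 0 and median 4."""
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(5 / 6)
        assert lookup[3.0] == pytest.approx(5 / 8)
        assert lookup[4.0] == pytest.approx(5 / 12)
        assert lookup[6.0] == pytest.approx(0.0)
        assert km.median == 4.0

    def test_curve_monotone_from_one(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        km = km_estimate(t, e)
        assert km.survival[0] == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


def _logrank_statistic(time, event, group):
    """Plain observed-minus-expected chi-square with hypergeometric variance."""
    order = np.argsort(time)
    time, event, group = time[order], event[order], group[order]
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = float(np.sum((time == t) & (event == 1)))
        n = float(at_risk.sum())
        n1 = float((at_risk & (group == 1)).sum())
        d1 = float(np.sum((time == t) & (event == 1) & (group == 1)))
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank_test(t, e, t.copy(), e.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_strong_separation_is_significant(self):
        a = np.arange(1.0, 9.0)
        b = np.arange(100.0, 108.0)
        _, p = logrank_test(a, np.ones(8, int), b, np.ones(8, int))
        assert p < 0.01

    def test_chi_square_p_agrees_with_exhaustive_permutation_oracle(self):
        """All 252 assignments of 10 subjects into 5+5 groups give the exact
        permutation distribution of the statistic; the chi-square p must sit
        close to that exact p."""
        time = np.array([1.0, 3.0, 4.0, 6.0, 7.0, 2.0, 5.0, 8.0, 9.0, 11.0])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 1, 0, 1])
        observed = _logrank_statistic(time, event, np.array([1] * 5 + [0] * 5))
        perm_stats = []
        for idx in itertools.combinations(range(10), 5):
            g = np.zeros(10, int)
            g[list(idx)] = 1
            perm_stats.append(_logrank_statistic(time, event, g))
        p_perm = np.mean(np.array(perm_stats) >= observed - 1e-12)
        stat, p_chi = logrank_test(time[:5], event[:5], time[5:], event[5:])
        assert stat == pytest.approx(observed, rel=1e-6)
        assert abs(p_chi - p_perm) < 0.06

    def test_invariant_under_group_swap(self):
        a, ea = np.array([1.0, 2.0, 5.0]), np.array([1, 1, 0])
        b, eb = np.array([3.0, 4.0, 6.0]), np.array([1, 0, 1])
        s1, p1 = logrank_test(a, ea, b, eb)
        s2, p2 = logrank_test(b, eb, a, ea)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


def fragment_frame(rng, shift, n_patients=10, n_fragments=3, between_sd=0.3, within_sd=0.2):
    rows = []
    for tissue, mu in (("adjacent_kidney", 1.0 + shift), ("ccRCC", 1.0)):
        for p in range(n_patients):
            pm = mu + rng.normal(0, between_sd)
            for f in range(n_fragments):
                rows.append(
                    {"patient": f"{tissue}-{p}", "tissue": tissue,
                     "value": pm + rng.normal(0, within_sd)}
                )
    return pd.DataFrame(rows)


class TestNestedComparison:
    def test_identical_class_means_give_large_p(self, rng):
        df = fragment_frame(rng, shift=0.0)
        res = nested_comparison(df, "adjacent_kidney", "ccRCC")
        assert res.p_value > 0.05  # no systematic difference injected

    def test_power_at_study_like_effect_size(self):
        """Class shift 1.0, patient SD 0.3, fragment SD 0.2, 10+10 patients
        x 3 fragments: rejects at alpha=0.05 in at least 90/100 seeds."""
        hits = 0
        for seed in range(100):
            df = fragment_frame(np.random.default_rng(seed), shift=1.0)
            res = nested_comparison(df, "adjacent_kidney", "ccRCC")
            hits += res.p_value < 0.05
        assert hits >= 90

    def test_balanced_case_equals_patient_means_t_test(self, rng):
        from scipy import stats

        df = fragment_frame(rng, shift=0.5)
        res = nested_comparison(df, "adjacent_kidney", "ccRCC")
        means = df.groupby(["tissue", "patient"])["value"].mean()
        t, p = stats.ttest_ind(
            means["adjacent_kidney"].to_numpy(), means["ccRCC"].to_numpy(), equal_var=True
        )
        assert res.p_value == pytest.approx(p)
        assert res.statistic == pytest.approx(t)

    def test_patient_summaries_include_sd_and_counts(self, rng):
        df = fragment_frame(rng, shift=0.5)
        res = nested_comparison(df, "adjacent_kidney", "ccRCC")
        assert set(res.patient_means.columns) >= {"patient", "tissue", "mean", "sd", "n_fragments"}
        assert (res.patient_means["n_fragments"] == 3).all()

    def test_too_few_patients_rejected(self):
        df = pd.DataFrame(
            {"patient": ["a", "b"], "tissue": ["ccRCC", "adjacent_kidney"], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError):
            nested_comparison(df, "adjacent_kidney", "ccRCC")


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_hand_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
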