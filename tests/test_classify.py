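import itertools
import math

import numpy as np
import pytest
from scipy import stats

import dielclass as dc


def rank_sum_z(a, b):
    """Independent tie-corrected standardized rank-sum (oracle helper)."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    r = stats.rankdata(np.concatenate([a, b]))
    w = r[:n1].sum()
    _, cnt = np.unique(np.concatenate([a, b]), return_counts=True)
    var = n1 * n2 / 12.0 * ((n + 1) - (cnt**3 - cnt).sum() / (n * (n - 1)))
    return (w - n1 * (n + 1) / 2.0) / math.sqrt(var) if var > 0 else 0.0


def exact_steel_dwass_p(groups, pair):
    """Exhaustive permutation reference for tie-free (4,4,4) fixtures.

    Enumerates every assignment of the 12 pooled values into three groups of
    four and returns the familywise tail probability of the maximum pairwise
    statistic exceeding the observed one for ``pair``.
    """
    vals = np.concatenate(groups)
    assert len(vals) == 12 and len(np.unique(vals)) == 12
    t_obs = math.sqrt(2) * abs(rank_sum_z(groups[pair[0]], groups[pair[1]]))
    idx = range(12)
    count = total = 0
    for a_idx in itertools.combinations(idx, 4):
        rest = [i for i in idx if i not in a_idx]
        for b_idx in itertools.combinations(rest, 4):
            c_idx = [i for i in rest if i not in b_idx]
            gs = [vals[list(a_idx)], vals[list(b_idx)], vals[c_idx]]
            t_max = max(
                math.sqrt(2) * abs(rank_sum_z(gs[i], gs[j]))
                for i, j in [(0, 1), (0, 2), (1, 2)]
            )
            count += t_max >= t_obs - 1e-9
            total += 1
    return count / total


class TestOnewayAnova:
    def test_identical_groups(self):
        g = [np.ones(5)] * 3
        assert dc.oneway_anova(g) == (0.0, 1.0)

    def test_separated_groups_with_jitter(self):
        rng = np.random.default_rng(0)
        j = lambda: rng.normal(0, 1e-6, 4)
        f, p = dc.oneway_anova([j(), 10 + j(), j()])
        assert p < 0.001

    def test_matches_sums_of_squares_decomposition(self):
        groups = [np.array([3.0, 5.0, 2.0, 6.0, 4.0]),
                  np.array([8.0, 9.0, 7.0, 10.0, 11.0]),
                  np.array([4.0, 6.0, 5.0, 3.0, 7.0])]
        # brute-force SS decomposition
        pooled = np.concatenate(groups)
        grand = pooled.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = 2, len(pooled) - 3
        f_oracle = (ss_between / df_b) / (ss_within / df_w)
        p_oracle = stats.f.sf(f_oracle, df_b, df_w)
        f, p = dc.oneway_anova(groups)
        assert f == pytest.approx(f_oracle, rel=1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            dc.oneway_anova([np.array([1.0]), np.array([1.0, 2.0]), np.array([1.0, 2.0])])


class TestSteelDwass:
    def test_identical_groups_give_p_one(self):
        g = [np.ones(5), np.ones(5), np.ones(5)]
        assert all(p == pytest.approx(1.0) for p in dc.steel_dwass(g).values())

    def test_matches_exhaustive_permutation_oracle_in_the_tail(self):
        """Fully separated groups: every pair sits in the decision tail, where
        the infinite-df studentized-range reference is meant to approximate
        the familywise permutation distribution."""
        groups = [np.array([1.0, 2, 3, 4]), np.array([11.0, 12, 13, 14]),
                  np.array([5.0, 6, 7, 8])]
        pw = dc.steel_dwass(groups)
        for pair, p in pw.items():
            assert abs(p - exact_steel_dwass_p(groups, pair)) <= 0.02

    def test_matches_permutation_oracle_at_the_null(self):
        """A pair with zero standardized statistic gets p = 1 from both the
        asymptotic reference and exhaustive enumeration."""
        groups = [np.array([1.0, 2, 5, 6]), np.array([3.0, 8, 10, 11]),
                  np.array([4.0, 7, 9, 12])]
        p = dc.steel_dwass(groups)[(1, 2)]
        assert p == pytest.approx(1.0)
        assert exact_steel_dwass_p(groups, (1, 2)) == pytest.approx(1.0)

    def test_two_group_statistic_equals_wilcoxon_normal_approximation(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 7)
        p = dc.steel_dwass([a, b])[(0, 1)]
        z = rank_sum_z(a, b)
        p_oracle = stats.studentized_range.sf(math.sqrt(2) * abs(z), 2, np.inf)
        assert p == pytest.approx(p_oracle, rel=1e-9)
        # with k = 2 the studentized range p equals the two-sided normal p
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-6)

    def test_ties_degrade_the_statistic(self):
        base = [np.array([1.0, 2, 3, 4, 5]), np.array([6.0, 7, 8, 9, 10])]
        tied = [np.array([1.0, 2, 3, 4, 5]), np.array([5.0, 7, 8, 9, 10])]
        more_tied = [np.array([1.0, 2, 3, 4, 5]), np.array([5.0, 4, 8, 9, 10])]
        ps = [dc.steel_dwass(g)[(0, 1)] for g in (base, tied, more_tied)]
        assert ps[0] < ps[1] < ps[2]


class TestAssignCategory:
    MEANS = {"twilight": 5.0, "day": 3.0, "night": 1.0}
    SIG = {("twilight", "day"): 0.001, ("twilight", "night"): 0.001, ("day", "night"): 0.001}

    def test_cathemeral_when_anova_not_significant(self):
        assert dc.assign_category(self.MEANS, 0.32, self.SIG) == "Ca"

    def test_simple_winner(self):
        assert dc.assign_category(self.MEANS, 1e-5, self.SIG) == "Cr"

    def test_composite_top_two(self):
        means = {"day": 4.0, "night": 4.5, "twilight": 1.0}
        pw = {("day", "night"): 0.8, ("twilight", "night"): 0.001, ("twilight", "day"): 0.001}
        assert dc.assign_category(means, 1e-4, pw) == "D/N"

    def test_composite_ordering_is_canonical(self):
        means = {"twilight": 4.2, "night": 4.5, "day": 1.0}
        pw = {("twilight", "night"): 0.8, ("day", "night"): 0.001, ("twilight", "day"): 0.001}
        assert dc.assign_category(means, 1e-4, pw) == "Cr/N"

    def test_undetermined_when_nothing_separates(self):
        pw = {k: 0.5 for k in self.SIG}
        assert dc.assign_category(self.MEANS, 0.01, pw) == "undetermined"

    @pytest.mark.parametrize("scale", [0.01, 1.0, 1e4])
    def test_scale_invariance(self, scale):
        means = {k: v * scale for k, v in self.MEANS.items()}
        assert dc.assign_category(means, 1e-5, self.SIG) == "Cr"


class TestClassifySpecies:
    def test_recovers_planted_categories(self, calendar, spring_survey):
        _, _, events, effort, truth = spring_survey
        freq = dc.daily_frequencies(events, effort, calendar)
        for name, expected in truth["planted_category"].items():
            result = dc.classify_species(freq, name, "spring")
            assert result.category == expected, name
            assert result.n_days == 90

    def test_empty_scope_is_undetermined(self, calendar, spring_survey):
        _, _, events, effort, _ = spring_survey
        freq = dc.daily_frequencies(events, effort, calendar)
        result = dc.classify_species(freq, "diurnal", "winter")
        assert result.category == "undetermined"
        assert math.isnan(result.anova_p)

    def test_classify_all_covers_species_by_scope(self, calendar, spring_survey):
        _, _, events, effort, _ = spring_survey
        freq = dc.daily_frequencies(events, effort, calendar)
        table = dc.classify_all(freq, scopes=["spring"])
        assert set(table["species"]) == {"diurnal", "nocturnal", "crepuscular", "uniform"}
        assert {"category", "anova_p", "twilight_mean", "day_se"} <= set(table.columns)
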