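"""Exact tests vs. enumeration oracles, GMT comparisons, table reconstruction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, hypergeom, mannwhitneyu

from seroclust import (
    ContingencyTable2x2,
    association_screen,
    counts_from_percent,
    fisher_exact_two_sided,
    mann_whitney_u,
    spearman_rho,
    table_from_percents,
    ttest_log_titers,
)
from seroclust.association_stats import AmbiguousPercentError, ConstantInputError
from seroclust.cohort import RO_LA, SERONEGATIVE, SM_RNP


# ---------------------------------------------------------------- oracles
def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-7):
            p += pk
    return min(p, 1.0)


def mannwhitney_oracle(x, y):
    """Exact two-sided p via pairwise-counting U over all label assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * len(y) / 2.0

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    dev = abs(u_obs - mu)
    hits = total = 0
    for subset in itertools.combinations(range(len(pooled)), nx):
        if abs(u_of(set(subset)) - mu) >= dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def spearman_oracle_p(x, y):
    """Exact permutation p using the sum-of-squared-rank-differences form."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    n = len(rx)

    def rho_of(perm):
        pr = np.asarray(perm)
        return float(np.corrcoef(pr, ry)[0, 1])

    rho_obs = rho_of(rx)
    hits = total = 0
    for perm in itertools.permutations(rx):
        if abs(rho_of(perm)) >= abs(rho_obs) - 1e-12:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------- Fisher
class TestFisherExact:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((0, 66, 8, 53), 0.0022),
            ((4, 7, 11, 107), 0.024),
            ((39, 10, 45, 35), 0.0079),
            ((11, 38, 4, 76), 0.0041),
        ],
    )
    def test_reproduces_printed_p_values(self, table, printed):
        res = fisher_exact_two_sided(ContingencyTable2x2(*table))
        assert float(f"{res.p_two_sided:.2g}") == printed

    def test_balanced_minimal_table(self):
        res = fisher_exact_two_sided(ContingencyTable2x2(1, 0, 0, 1))
        assert res.p_two_sided == 1.0

    def test_zero_margin_defined_as_one_with_warning(self):
        with pytest.warns(UserWarning, match="empty margin"):
            res = fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 5))
        assert res.p_two_sided == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 200:
            counts = rng.integers(0, 11, size=4)
            if counts.sum() < 1:
                continue
            a, b, c, d = (int(v) for v in counts)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            res = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
            assert res.p_two_sided == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)
            checked += 1

    def test_invariance_under_transpose_and_double_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 12, size=4))
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_two_sided
            p_t = fisher_exact_two_sided(ContingencyTable2x2(a, c, b, d)).p_two_sided
            p_s = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a)).p_two_sided
            assert p_t == pytest.approx(p, rel=1e-12)
            assert p_s == pytest.approx(p, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------- Mann-Whitney
class TestMannWhitney:
    def test_complete_separation_small_n(self):
        res = mann_whitney_u([1, 2, 3], [10, 20, 30])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples(self):
        res = mann_whitney_u([5, 5, 7, 9], [5, 5, 7, 9])
        assert res.statistic == pytest.approx(8.0)  # n^2 / 2
        assert res.p_two_sided == 1.0

    def test_exact_matches_pairwise_counting_oracle(self):
        """Independent oracle counts U by pairwise comparison; the
        implementation enumerates midrank sums. 200 random tied instances."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.integers(0, 5, nx).tolist()  # heavy ties
            y = rng.integers(0, 5, ny).tolist()
            res = mann_whitney_u(x, y)
            assert res.p_two_sided == pytest.approx(mannwhitney_oracle(x, y), abs=1e-12)

    def test_exact_matches_scipy_for_untied_data(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            perm = rng.permutation(100).astype(float)
            x, y = perm[:6], perm[6:13]
            res = mann_whitney_u(list(x), list(y))
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_two_sided == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n10(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(0.3, size=10)
            exact = mann_whitney_u(x, y, exact_max_n=20).p_two_sided
            approx = mann_whitney_u(x, y, exact_max_n=0).p_two_sided
            assert abs(exact - approx) < 0.01

    def test_rank_invariance_under_shift(self):
        x = [3.0, 1.0, 4.0, 1.5]
        y = [9.0, 2.6, 5.3, 5.8]
        a = mann_whitney_u(x, y)
        b = mann_whitney_u([v + 1000 for v in x], [v + 1000 for v in y])
        assert a.statistic == b.statistic
        assert a.p_two_sided == b.p_two_sided


# ---------------------------------------------------------------- t-test / GMT
class TestLogTiterTTest:
    def test_geometric_mean(self):
        res = ttest_log_titers([10.0, 1000.0], [10.0, 1000.0])
        assert res.effect["gmt_x"] == pytest.approx(100.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        """Under the null (same log-normal), rejections at alpha=0.05 over
        1,000 simulated tests stay inside the exact binomial 99% interval."""
        rng = np.random.default_rng(41)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = 10 ** rng.normal(3.0, 0.4, size=10)
            y = 10 ** rng.normal(3.0, 0.4, size=10)
            if ttest_log_titers(x, y).p_two_sided < 0.05:
                rejections += 1
        lo, hi = binom.ppf([0.005, 0.995], n_sim, 0.05)
        assert lo <= rejections <= hi

    def test_recovers_known_log_offset(self):
        rng = np.random.default_rng(43)
        x = 10 ** rng.normal(3.5, 0.3, size=400)
        y = 10 ** rng.normal(3.0, 0.3, size=400)
        res = ttest_log_titers(x, y)
        assert np.log10(res.effect["gmt_ratio"]) == pytest.approx(0.5, abs=0.06)

    def test_nonpositive_titers_rejected(self):
        with pytest.raises(ValueError):
            ttest_log_titers([1.0, 0.0], [1.0, 2.0])


# ---------------------------------------------------------------- Spearman
class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 5, 8]
        assert spearman_rho(x, [2, 4, 9, 10, 30]).statistic == pytest.approx(1.0)
        assert spearman_rho(x, [30, 10, 9, 4, 2]).statistic == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_exact_permutation_matches_oracle_n8(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            x = rng.normal(size=8)
            y = 0.5 * x + rng.normal(size=8)
            res = spearman_rho(x, y)
            assert res.p_two_sided == pytest.approx(spearman_oracle_p(x, y), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(53)
        x = rng.lognormal(size=15)
        y = rng.lognormal(size=15)
        a = spearman_rho(x, y)
        b = spearman_rho(np.log(x), y**2)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)


# ------------------------------------------------------- percent bookkeeping
class TestCountsFromPercent:
    @pytest.mark.parametrize(
        "pct,n,expected",
        [(13, 61, 8), (0, 66, 0), (80, 49, 39), (56, 80, 45), (36, 129, 46)],
    )
    def test_reconstruction(self, pct, n, expected):
        assert counts_from_percent(pct, n) == expected

    def test_joint_consistency_with_marginal(self):
        # 39/49 + 45/80 = 84 = the printed 65% of 129 anti-Sm positives
        total = counts_from_percent(80, 49) + counts_from_percent(56, 80)
        assert total == counts_from_percent(65, 129) == 84

    def test_ambiguous_reconstruction_raises(self):
        with pytest.raises(AmbiguousPercentError, match="candidates"):
            counts_from_percent(50, 3)

    def test_table_from_percents(self):
        tab = table_from_percents(0, 66, 13, 61)
        assert (tab.a, tab.b, tab.c, tab.d) == (0, 66, 8, 53)


# ---------------------------------------------------------------- screen
def _quick_cohort(labels, flag):
    """Minimal cohort + assignments carrying one binary feature."""
    from seroclust import CohortTable

    n = len(labels)
    idx = [f"P{i}" for i in range(n)]
    data = pd.DataFrame(
        {"group": "SLE", "serositis": flag, "Sm-D3": 100.0},
        index=pd.Index(idx, name="patient_id"),
    )
    cohort = CohortTable(data, ["Sm-D3"])
    assignments = pd.DataFrame(
        {"label": labels, "rr": 1.0, "pure": False},
        index=pd.Index(idx, name="patient_id"),
    )
    return cohort, assignments


class TestAssociationScreen:
    def test_detection_rate_matches_exact_power_oracle(self):
        """Serositis at 13% in Sm/RNP and 0% in Ro/La, cohorts of n=127:
        the screen's detection rate at alpha=0.05 over 500 simulated cohorts
        agrees with the exact conditional power computed by enumeration."""
        rng = np.random.default_rng(59)
        n_sim, alpha = 500, 0.05
        detected = 0
        expected_power = []
        power_cache: dict[tuple[int, int], float] = {}

        def exact_power(n_sm: int, n_ro: int) -> float:
            # enumeration is only needed up to modest k; beyond that the
            # table is overwhelmingly significant and pmf mass negligible
            if (n_sm, n_ro) not in power_cache:
                power_cache[(n_sm, n_ro)] = sum(
                    binom.pmf(k, n_sm, 0.13)
                    for k in range(n_sm + 1)
                    if k > 30 or fisher_oracle(k, n_sm - k, 0, n_ro) < alpha
                )
            return power_cache[(n_sm, n_ro)]

        for _ in range(n_sim):
            sizes = rng.multinomial(127, [0.47, 0.51, 0.02])
            labels = (
                [SM_RNP] * sizes[0] + [RO_LA] * sizes[1] + [SERONEGATIVE] * sizes[2]
            )
            flag = np.concatenate(
                [
                    rng.random(sizes[0]) < 0.13,
                    np.zeros(sizes[1], dtype=bool),
                    np.zeros(sizes[2], dtype=bool),
                ]
            ).astype(int)
            cohort, assignments = _quick_cohort(labels, flag)
            out = association_screen(cohort, assignments, ["serositis"])
            if out.loc["serositis", "p"] < alpha:
                detected += 1
            expected_power.append(exact_power(int(sizes[0]), int(sizes[1])))
        mean_power = float(np.mean(expected_power))
        lo, hi = binom.ppf([0.005, 0.995], n_sim, mean_power)
        assert lo <= detected <= hi
        assert mean_power > 0.85  # the association is reliably detectable

    def test_null_p_values_are_valid(self):
        """With the feature independent of cluster, P(p <= alpha) <= alpha
        (exact conditional tests are conservative, not uniform)."""
        rng = np.random.default_rng(61)
        pvals = []
        for _ in range(400):
            labels = [SM_RNP] * 60 + [RO_LA] * 67
            flag = (rng.random(127) < 0.2).astype(int)
            cohort, assignments = _quick_cohort(labels, flag)
            out = association_screen(cohort, assignments, ["serositis"])
            pvals.append(out.loc["serositis", "p"])
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            rate = (pvals <= alpha).mean()
            mc = 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert rate <= alpha + mc

    def test_bh_column_present_and_ordered(self, sim_cohort):
        from seroclust import assign_clusters, fit_control_cutoffs

        cohort, _ = sim_cohort
        assignments = assign_clusters(cohort, fit_control_cutoffs(cohort))
        out = association_screen(
            cohort, assignments, ["serositis", "nephritis", "cns", "musculoskeletal"]
        )
        assert "p_bh" in out.columns
        assert (out["p_bh"] >= out["p"] - 1e-12).all()

    def test_empty_stratum_skipped_with_warning(self):
        labels = [SM_RNP] * 10  # no Ro/La stratum at all
        cohort, assignments = _quick_cohort(labels, [0, 1] * 5)
        with pytest.warns(UserWarning, match="empty stratum"):
            out = association_screen(cohort, assignments, ["serositis"])
        assert len(out) == 0
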