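"""Rank statistics, Hardy-Weinberg, NPI totals and correlation tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scnmap import (
    build_correlation_tables,
    group_comparison_table,
    hwe_chisq,
    mann_whitney,
    npi_total,
    spearman,
)


def mw_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all label assignments of the
    pooled sample (valid when there are no ties)."""
    pooled = list(x) + list(y)
    nx = len(x)
    obs = sum(1 for xi in x for yj in y if xi > yj)
    stats_all = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        stats_all.append(sum(1 for xi in xs for yj in ys if xi > yj))
    stats_all = np.asarray(stats_all)
    mu = nx * len(y) / 2
    # two-sided: as or more extreme in |U - mean|
    p = np.mean(np.abs(stats_all - mu) >= abs(obs - mu))
    return float(p)


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.p == pytest.approx(mw_enumeration_oracle([1, 2, 3], [10, 11, 12]))

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "asymptotic"  # ties force the approximation
        assert res.p == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(0.5, 1.0, size=8)
        r1 = mann_whitney(x, y)
        r2 = mann_whitney(np.exp(x), np.exp(y))
        assert r1.u == r2.u
        assert r1.p == pytest.approx(r2.p)

    def test_exact_and_asymptotic_agree_at_n12(self):
        # the two computational paths agree within 0.02 absolute p
        rng = np.random.default_rng(1)
        from scipy import stats as sps

        for _ in range(25):
            x = rng.normal(size=12)
            y = rng.normal(0.3, 1.0, size=12)
            exact = mann_whitney(x, y)
            assert exact.method == "exact"
            approx = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            assert abs(exact.p - approx.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -np.exp(x)).rho == pytest.approx(-1.0)

    def test_tied_example_matches_rank_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0, 6.0])
        # oracle: explicit average ranks then the Pearson formula
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        rho_oracle = (rxc @ ryc) / np.sqrt((rxc @ rxc) * (ryc @ ryc))
        assert spearman(x, y).rho == pytest.approx(rho_oracle, abs=1e-10)

    def test_matches_scipy_unadjusted(self):
        rng = np.random.default_rng(2)
        from scipy import stats as sps

        x, y = rng.normal(size=25), rng.normal(size=25)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_adjusted_equals_unadjusted_for_constant_covariate(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        plain = spearman(x, y)
        adj = spearman(x, y, adjust={"c": np.full(20, 3.0)})
        assert adj.rho == pytest.approx(plain.rho, abs=1e-10)

    def test_adjusted_matches_pingouin_partial(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        n = 40
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = 0.5 * z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ours = spearman(x, y, adjust={"z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert ours.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_adjustment_removes_confounding(self):
        rng = np.random.default_rng(5)
        n = 200
        z = rng.normal(size=n)
        x = z + 0.3 * rng.normal(size=n)
        y = z + 0.3 * rng.normal(size=n)
        assert spearman(x, y).rho > 0.7
        assert abs(spearman(x, y, adjust={"z": z}).rho) < 0.3

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestHWE:
    def test_exact_proportions_give_zero(self):
        chi2, p = hwe_chisq(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        chi2, _ = hwe_chisq(49, 42, 9)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_zero(self):
        assert hwe_chisq(100, 0, 0)[0] == 0.0

    def test_random_counts_match_direct_formula(self, rng):
        for _ in range(20):
            counts = rng.multinomial(104, [0.5, 0.35, 0.15])
            chi2, _ = hwe_chisq(*counts)
            n = counts.sum()
            p_hat = (2 * counts[0] + counts[1]) / (2 * n)
            expected = n * np.array(
                [p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2]
            )
            oracle = float(((counts - expected) ** 2 / expected).sum())
            assert chi2 == pytest.approx(oracle, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_chisq(-1, 2, 3)


class TestNPI:
    def test_ceiling(self):
        assert npi_total([(4, 3)] * 12) == 144

    def test_floor_and_single_item(self):
        assert npi_total([(0, 0)] * 12) == 0
        items = [(0, 0)] * 12
        items[4] = (2, 3)
        assert npi_total(items) == 6

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 3)),
            min_size=12, max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_total_in_range(self, items):
        assert 0 <= npi_total(items) <= 144

    def test_out_of_range_rejected(self):
        items = [(0, 0)] * 12
        items[0] = (5, 0)
        with pytest.raises(ValueError):
            npi_total(items)


class TestTables:
    def _cohort(self, rng, n=40):
        volume = rng.normal(1.0, 0.2, size=n)
        cohort = pd.DataFrame(
            {
                "stratum": ["G"] * (n // 2) + ["AA"] * (n - n // 2),
                "age": rng.normal(72, 7, size=n),
                "education": rng.normal(6, 4, size=n),
                "linked": 2.0 * volume,  # noise-free monotone link
                "unlinked": rng.normal(size=n),
            }
        )
        volumes = pd.DataFrame({"seed_a": volume}, index=cohort.index)
        return cohort, volumes

    def test_planted_link_is_perfect_and_flagged(self, rng):
        cohort, volumes = self._cohort(rng)
        tables = build_correlation_tables(
            cohort, volumes, ["linked", "unlinked"], adjust=()
        )
        for stratum in ("G", "AA"):
            assert tables.rho.loc["linked", ("seed_a", stratum)] == pytest.approx(1.0)
            assert tables.flags.loc["linked", ("seed_a", stratum)] == "b"

    def test_shape_contract(self, rng):
        cohort, volumes = self._cohort(rng)
        volumes["seed_b"] = rng.normal(size=len(cohort))
        tables = build_correlation_tables(cohort, volumes, ["linked", "unlinked"])
        assert tables.rho.shape == (2, 4)  # tests x (volumes x strata)
        assert tables.n.loc["linked", ("seed_a", "G")] == 20

    def test_pairwise_complete_with_missing_scores(self, rng):
        cohort, volumes = self._cohort(rng)
        cohort.loc[0:4, "unlinked"] = np.nan
        tables = build_correlation_tables(cohort, volumes, ["unlinked"], adjust=())
        assert tables.n.loc["unlinked", ("seed_a", "G")] == 15

    def test_group_comparison_table(self, rng):
        cohort, _ = self._cohort(rng)
        table = group_comparison_table(cohort, ["age", "education"])
        assert set(table["variable"]) == {"age", "education"}
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()
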