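import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multinomial as sp_multinomial

from psimeth.site_test import (
    ContingencyTable,
    SkipSite,
    build_table,
    exact_pvalue,
    independence_probs,
    permutation_pvalue,
    rms_statistic,
    select_cutoff,
    site_seed,
    run_site_tests,
)


def brute_force_tail_probability(counts: np.ndarray) -> float:
    """Independent enumeration oracle for the exact RMS tail probability.

    Walks every composition of n reads over the table's cells via
    itertools and accumulates multinomial pmf mass where the simulated
    statistic reaches the observed one.
    """
    counts = np.asarray(counts)
    n = int(counts.sum())
    probs = independence_probs(ContingencyTable(counts)).ravel()
    probs = probs / probs.sum()
    obs = rms_statistic(counts)
    k = probs.size
    total = 0.0
    for cells in itertools.product(range(n + 1), repeat=k - 1):
        last = n - sum(cells)
        if last < 0:
            continue
        arr = np.array(cells + (last,))
        if (arr[probs == 0] > 0).any():
            continue
        if rms_statistic(arr.reshape(counts.shape)) >= obs - 1e-12:
            total += float(sp_multinomial.pmf(arr, n, probs))
    return total


class TestRmsStatistic:
    def test_independent_table_is_zero(self):
        assert rms_statistic(np.array([[10, 10], [10, 10]])) == pytest.approx(0.0)

    def test_diagonal_table_value(self):
        # f = diag(0.5), e = 0.25 everywhere -> sqrt(mean(4 * 0.0625)) = 0.25
        assert rms_statistic(np.array([[20, 0], [0, 20]])) == pytest.approx(0.25)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_row_and_column_symmetries(self, rows, rnd):
        counts = np.array(rows)
        if counts.sum() == 0:
            return
        stat = rms_statistic(counts)
        perm = list(range(len(rows)))
        rnd.shuffle(perm)
        assert rms_statistic(counts[perm]) == pytest.approx(stat)
        assert rms_statistic(counts[:, ::-1]) == pytest.approx(stat)


class TestBuildTable:
    def test_rows_are_samples(self):
        t = build_table(np.array([3, 7]), np.array([10, 10]), ["a", "b"])
        assert t.counts.tolist() == [[3, 7], [7, 3]]
        assert t.group_labels == ("a", "b")

    def test_zero_coverage_row_omitted(self):
        t = build_table(np.array([3, 0, 7]), np.array([10, 0, 10]), ["a", "a", "b"])
        assert t.counts.shape == (2, 2)

    def test_single_covered_sample_skips(self):
        with pytest.raises(SkipSite):
            build_table(np.array([3, 0]), np.array([10, 0]), ["a", "b"])

    def test_uncovered_group_skips(self):
        with pytest.raises(SkipSite):
            build_table(np.array([3, 4, 0]), np.array([10, 10, 0]), ["a", "a", "b"])


class TestPermutationPvalue:
    def test_zero_statistic_stops_at_floor(self):
        t = ContingencyTable(np.array([[10, 10], [10, 10]]))
        stat, p, run, exceed, early = permutation_pvalue(t, seed=1)
        assert stat == 0.0
        assert (run, exceed, early) == (100, 100, True)
        assert p == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        t = ContingencyTable(np.array([[8, 2], [3, 7], [5, 5]]))
        r1 = permutation_pvalue(t, max_perms=500, seed=42)
        r2 = permutation_pvalue(t, max_perms=500, seed=42)
        assert r1 == r2
        r3 = permutation_pvalue(t, max_perms=500, seed=43)
        assert r3 != r1  # different stream actually sampled

    def test_strong_table_matches_monte_carlo_oracle(self, rng):
        """[[50,0],[0,50]] against a large vectorized Monte-Carlo oracle."""
        counts = np.array([[50, 0], [0, 50]])
        t = ContingencyTable(counts)
        obs = rms_statistic(counts)
        probs = independence_probs(t).ravel()
        n_rep = 1_000_000
        draws = rng.multinomial(100, probs, size=n_rep).reshape(n_rep, 2, 2)
        nn = draws.sum(axis=(1, 2), keepdims=True)
        f = draws / nn
        e = f.sum(axis=2, keepdims=True) * f.sum(axis=1, keepdims=True)
        stats = np.sqrt(np.mean((f - e) ** 2, axis=(1, 2)))
        p_oracle = float((stats >= obs - 1e-12).mean())
        sd = np.sqrt(max(p_oracle, 1e-9) * (1 - p_oracle) / n_rep)

        _, p, run, _, _ = permutation_pvalue(t, max_perms=20_000, stop_exceedances=20_001, seed=7)
        assert p <= 0.01
        assert abs(p - p_oracle) <= 3 * np.sqrt(p_oracle * (1 - p_oracle) / run) + 3 * sd + 2 / run

    def test_tiny_table_converges_to_enumeration(self):
        counts = np.array([[2, 0], [0, 2]])
        t = ContingencyTable(counts)
        p_exact = brute_force_tail_probability(counts)
        n = 40_000
        _, p_mc, run, _, early = permutation_pvalue(t, max_perms=n, stop_exceedances=n + 1, seed=3)
        assert not early
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / n) + 2 / n
        assert abs(p_mc - p_exact) <= tol

    def test_requires_seed(self):
        t = ContingencyTable(np.array([[1, 1], [1, 1]]))
        with pytest.raises(ValueError, match="seed"):
            permutation_pvalue(t)


class TestExactPvalue:
    @pytest.mark.parametrize(
        "counts",
        [[[2, 0], [0, 2]], [[3, 1], [0, 2]], [[1, 1], [1, 1]], [[4, 0], [0, 1]]],
    )
    def test_matches_brute_force(self, counts):
        counts = np.array(counts)
        assert exact_pvalue(ContingencyTable(counts)) == pytest.approx(
            brute_force_tail_probability(counts), abs=1e-12
        )


class TestSelectCutoff:
    def test_all_ones_nothing_significant(self):
        cal = select_cutoff(np.ones(100), 0.01)
        assert cal.n_significant == 0 and cal.pvalue_cutoff == 0.0

    def test_bh_step_up_example(self):
        """Brute-force over all candidate cutoffs of the step-up rule."""
        p = np.array([0.001, 0.011, 0.02, 0.8, 0.9])
        cal = select_cutoff(p, 0.05)
        # by hand: p_(3)=0.02 <= 3*0.05/5=0.03 is the largest passing rank
        best = 0.0
        for k, pk in enumerate(np.sort(p), 1):
            if pk <= k * 0.05 / len(p):
                best = pk
        assert cal.pvalue_cutoff == pytest.approx(best) == pytest.approx(0.02)
        assert cal.n_significant == 3

    def test_empirical_null_with_identical_null_rejects_nothing(self):
        p = np.array([0.001, 0.02, 0.5, 0.9])
        cal = select_cutoff(p, 0.05, "empirical_null", null_p=p)
        assert cal.n_significant == 0

    def test_empirical_null_with_clean_null(self):
        obs = np.array([0.001, 0.002, 0.6, 0.7])
        null = np.array([0.5, 0.6, 0.7, 0.8])
        cal = select_cutoff(obs, 0.05, "empirical_null", null_p=null)
        assert cal.n_significant == 2

    def test_bh_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            m = int(rng.integers(1, 60))
            p = rng.uniform(size=m)
            cal = select_cutoff(p, 0.05)
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert cal.n_significant == int(reject.sum())
            if cal.n_significant:
                assert set(np.nonzero(p <= cal.pvalue_cutoff)[0]) == set(np.nonzero(reject)[0])


class TestTestAllSites:
    @staticmethod
    def _null_frame(rng, n_sites=60, n_per_group=3):
        n_samp = 2 * n_per_group
        total = rng.poisson(15, (n_sites, n_samp)) + 1
        mc = rng.binomial(total, 0.2)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, n_sites + 1) * 10,
             "strand": "+", "context": "CG"}
        )
        labels = ["c"] * n_per_group + ["s"] * n_per_group
        return sites, mc, total, labels

    def test_null_pvalues_superuniform(self, rng):
        """Common-proportion multinomial null: ECDF(c) must not exceed c by
        more than Monte-Carlo tolerance at any grid point."""
        sites, mc, total, labels = self._null_frame(rng, n_sites=400)
        res = run_site_tests(sites, mc, total, labels, "c", "s",
                             max_perms=400, master_seed=5)
        p = res["pvalue"].to_numpy()
        for c in (0.01, 0.05, 0.1, 0.25, 0.5):
            ecdf = (p <= c).mean()
            assert ecdf <= c + 3 * np.sqrt(c * (1 - c) / len(p))

    def test_order_independence_via_derived_seeds(self, rng):
        sites, mc, total, labels = self._null_frame(rng)
        res = run_site_tests(sites, mc, total, labels, "c", "s",
                             max_perms=200, master_seed=9)
        perm = rng.permutation(len(sites))
        res2 = run_site_tests(sites.iloc[perm].reset_index(drop=True),
                              mc[perm], total[perm], labels, "c", "s",
                              max_perms=200, master_seed=9)
        merged = res.merge(res2, on="pos", suffixes=("_a", "_b"))
        assert len(merged) == len(res)
        assert np.allclose(merged["pvalue_a"], merged["pvalue_b"])
        assert np.allclose(merged["stat_a"], merged["stat_b"])

    def test_direction_from_pooled_levels(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [1, 2], "strand": "+", "context": "CHH"}
        )
        mc = np.array([[0, 0, 9, 9], [9, 9, 0, 0]])
        total = np.array([[10, 10, 10, 10]] * 2)
        res = run_site_tests(sites, mc, total, ["c", "c", "s", "s"], "c", "s",
                             max_perms=100, master_seed=1)
        assert res.set_index("pos").loc[1, "direction"] == "hyper"
        assert res.set_index("pos").loc[2, "direction"] == "hypo"

    def test_site_seed_stability(self):
        s1 = site_seed(3, "chr1", 100).generate_state(4)
        s2 = site_seed(3, "chr1", 100).generate_state(4)
        s3 = site_seed(3, "chr1", 101).generate_state(4)
        assert (s1 == s2).all() and not (s1 == s3).all()
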