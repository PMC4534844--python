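import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psimeth.synthetic_data import simulate_dmr_level_matrix
from psimeth.temporal_expression import (
    UntestableError,
    benjamini_hochberg,
    classify_persistence,
    cluster_samples,
    compare_groups,
    group_ttest,
    linkage_to_newick,
    onset_summary,
)


def welch_by_hand(a, b):
    """Closed-form Welch statistic, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


class TestGroupTtest:
    def test_zero_variance_untestable(self):
        with pytest.raises(UntestableError):
            group_ttest([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])

    def test_too_few_replicates_untestable(self):
        with pytest.raises(UntestableError):
            group_ttest([0.5], [0.4, 0.6])

    def test_separated_groups_significant(self):
        a, b = [0.1, 0.12, 0.11], [0.6, 0.58, 0.62]
        t, p = group_ttest(a, b)
        assert p < 0.001
        t_hand, _ = welch_by_hand(a, b)
        assert t == pytest.approx(t_hand)

    def test_jittered_self_comparison_near_one(self):
        a = np.array([0.1, 0.3, 0.5])
        t, p = group_ttest(a, a + 1e-9)
        assert p > 0.99

    def test_nan_levels_dropped(self):
        t, p = group_ttest([0.1, 0.12, np.nan, 0.11], [0.6, 0.58, 0.62])
        t2, p2 = group_ttest([0.1, 0.12, 0.11], [0.6, 0.58, 0.62])
        assert (t, p) == (t2, p2)


class TestBenjaminiHochberg:
    def test_single_pvalue_identity(self):
        assert benjamini_hochberg([0.03]).tolist() == [0.03]

    def test_step_up_by_hand(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 -> then monotone from the right
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert benjamini_hochberg([0.5, 0.5]) == pytest.approx([0.5, 0.5])

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms(use_true_random=False))
    def test_monotone_and_permutation_invariant(self, ps, rnd):
        q = benjamini_hochberg(ps)
        order = np.argsort(ps, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = benjamini_hochberg(np.asarray(ps)[perm])
        assert np.allclose(q_perm, q[perm])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(benjamini_hochberg(p), q_ref)


def _matrix(rows: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


SAMPLES = [f"{g}_r{i}" for g in ("plus_pi", "minus_pi", "resupply") for i in (1, 2, 3)]
GROUP_OF = {s: s.rsplit("_", 1)[0] for s in SAMPLES}


class TestClassifyPersistence:
    def test_spx2_like_worked_example(self):
        """Hypomethylation from ~50% to ~1.3% under stress, staying at
        ~1.5% after a month of resupply, is a persistent DMR."""
        m = _matrix(
            {"spx2_dmr": [0.50, 0.52, 0.48, 0.013, 0.012, 0.014, 0.015, 0.016, 0.014]},
            SAMPLES,
        )
        calls = classify_persistence(m, GROUP_OF)
        assert calls[0].call == "persistent"
        assert calls[0].q_stress_vs_control < 0.05 <= calls[0].q_stress_vs_recovery

    def test_reverting_dmr_is_transient(self):
        m = _matrix(
            {"d": [0.10, 0.11, 0.09, 0.42, 0.40, 0.41, 0.12, 0.10, 0.11]},
            SAMPLES,
        )
        assert classify_persistence(m, GROUP_OF)[0].call == "transient"

    def test_flat_dmr_is_ambiguous(self):
        m = _matrix({"d": [0.3, 0.31, 0.29, 0.3, 0.29, 0.31, 0.3, 0.3, 0.31]}, SAMPLES)
        assert classify_persistence(m, GROUP_OF)[0].call == "ambiguous"

    def test_recovery_alpha_is_configurable(self):
        m = _matrix(
            {"d": [0.10, 0.11, 0.09, 0.42, 0.40, 0.41, 0.12, 0.10, 0.11]},
            SAMPLES,
        )
        strict = classify_persistence(m, GROUP_OF, alpha=1e-9)
        assert strict[0].call == "ambiguous"  # nothing clears an impossible bar

    def test_generator_truth_recovery(self):
        matrix, group_of, truth = simulate_dmr_level_matrix(seed=4)
        calls = classify_persistence(matrix, group_of)
        tested = [(c.call, t) for c, t in zip(calls, truth) if t != "none"]
        correct = sum(1 for call, t in tested if call == t)
        assert correct / len(tested) >= 0.9


class TestCompareGroups:
    def test_bh_within_comparison_family(self):
        rng = np.random.default_rng(0)
        rows = {f"d{i}": list(rng.normal(0.3, 0.01, 9)) for i in range(5)}
        rows["hit"] = [0.1] * 3 + [0.6] * 3 + [0.3] * 3
        m = _matrix(rows, SAMPLES)
        out = compare_groups(m, GROUP_OF, "plus_pi", "minus_pi").set_index("dmr_id")
        assert out.loc["hit", "qvalue"] < 0.05
        assert out.loc["hit", "mean_a"] == pytest.approx(0.1)
        assert out.loc["hit", "mean_b"] == pytest.approx(0.6)

    def test_untestable_rows_excluded_from_family(self):
        m = _matrix({"flat": [0.2] * 9, "ok": [0.1, 0.12, 0.11, 0.6, 0.61, 0.59, 0.3, 0.3, 0.31]},
                    SAMPLES)
        out = compare_groups(m, GROUP_OF, "plus_pi", "minus_pi").set_index("dmr_id")
        assert np.isnan(out.loc["flat", "pvalue"]) and np.isnan(out.loc["flat", "qvalue"])
        assert out.loc["ok", "qvalue"] < 0.05


class TestOnsetSummary:
    def test_expression_precedes_methylation(self):
        """Expression flips at the first timepoint, methylation only at the
        last; the DE fraction must lead the DM fraction."""
        rng = np.random.default_rng(1)
        samples6 = [f"{g}_r{i}" for g in ("plus_pi", "minus_pi") for i in (1, 2, 3)]
        group6 = {s: s.rsplit("_", 1)[0] for s in samples6}
        dmr_genes = {f"d{i}": f"g{i}" for i in range(10)}

        def meth_matrix(effect: bool):
            rows = {}
            for i in range(10):
                base = list(rng.normal(0.1, 0.01, 3))
                alt = list(rng.normal(0.5 if effect else 0.1, 0.01, 3))
                rows[f"d{i}"] = base + alt
            return _matrix(rows, samples6)

        def de_table(effect: bool):
            return pd.DataFrame(
                {"gene_id": [f"g{i}" for i in range(10)],
                 "qvalue": [0.001 if effect else 0.5] * 10}
            )

        levels = {1: meth_matrix(False), 2: meth_matrix(False), 3: meth_matrix(True)}
        groups = {t: group6 for t in levels}
        de = {1: de_table(True), 2: de_table(True), 3: de_table(True)}
        out = onset_summary(levels, groups, de, dmr_genes)
        fr_de = [o.frac_genes_de for o in out]
        fr_dm = [o.frac_dmrs_dm for o in out]
        assert fr_de[0] > 0.9 and fr_dm[0] < 0.2
        assert fr_dm[2] > 0.9

    def test_mismatched_timepoints_error(self):
        with pytest.raises(ValueError):
            onset_summary({1: None}, {1: {}}, {2: None}, {})


class TestClusterSamples:
    def test_identical_pair_merges_first(self):
        m = pd.DataFrame(
            {"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3], "c": [0.9, 0.8, 0.7]},
            index=["d1", "d2", "d3"],
        )
        link, leaves = cluster_samples(m)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}  # a and b merge first
        assert link[0, 2] == pytest.approx(0.0)
        assert abs(leaves.index("a") - leaves.index("b")) == 1

    def test_condition_blocks_separate(self, rng):
        n_dmr = 30
        cols = {}
        for i in range(4):
            cols[f"ctrl{i}"] = rng.normal(0.1, 0.02, n_dmr)
        for i in range(4):
            cols[f"strs{i}"] = rng.normal(0.6, 0.02, n_dmr)
        m = pd.DataFrame(cols)
        _, leaves = cluster_samples(m)
        first_half = {l[:4] for l in leaves[:4]}
        assert first_half in ({"ctrl"}, {"strs"})

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"a": [0.1, 0.2]}))

    def test_newick_export_parses(self):
        import dendropy

        m = pd.DataFrame(
            {"a": [0.1, 0.2], "b": [0.15, 0.22], "c": [0.9, 0.8], "d": [0.88, 0.79]},
            index=["d1", "d2"],
        )
        link, _ = cluster_samples(m)
        nwk = linkage_to_newick(link, list(m.columns))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == {"a", "b", "c", "d"}
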