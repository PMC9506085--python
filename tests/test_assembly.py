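import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from aquacomm import assembly, synthdata
from aquacomm._exceptions import AlignmentError
from conftest import random_count_table


def brute_force_betamntd(table: pd.DataFrame, tree: TreeNode, weighted=True):
    """Naive double-loop oracle for betaMNTD."""
    dm = tree.tip_tip_distances()
    taxa = list(table.index)
    samples = list(table.columns)
    out = np.zeros((len(samples), len(samples)))
    for a in range(len(samples)):
        for b in range(len(samples)):
            if a == b:
                continue
            total = 0.0
            for src, dst in ((a, b), (b, a)):
                src_col = table.iloc[:, src]
                dst_col = table.iloc[:, dst]
                present_src = [t for t in taxa if src_col[t] > 0]
                present_dst = [t for t in taxa if dst_col[t] > 0]
                if weighted:
                    denom = src_col.sum()
                    weights = {t: src_col[t] / denom for t in present_src}
                else:
                    weights = {t: 1.0 / len(present_src) for t in present_src}
                for t in present_src:
                    nearest = min(dm[(t, u)] for u in present_dst)
                    total += weights[t] * nearest
            out[a, b] = 0.5 * total
    return out


class TestBetaMntd:
    def test_identical_communities_zero(self, toy_tree):
        table = pd.DataFrame({"s1": [2, 1, 3], "s2": [2, 1, 3]}, index=["A", "B", "C"])
        bm = assembly.beta_mntd(table, toy_tree)
        assert bm[("s1", "s2")] == pytest.approx(0.0)

    def test_disjoint_singletons_hand_value(self, toy_tree):
        # sample1 = {A}, sample2 = {C}: patristic d(A, C) = 2 + 2 = 4
        table = pd.DataFrame({"s1": [1, 0, 0], "s2": [0, 0, 1]}, index=["A", "B", "C"])
        bm = assembly.beta_mntd(table, toy_tree)
        assert bm[("s1", "s2")] == pytest.approx(4.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, rng, weighted):
        tree = synthdata.simulate_tree(6, seed=5)
        table = random_count_table(rng, n_taxa=6, n_samples=4, depth=60)
        table.index = [f"OTU_{i + 1}" for i in range(6)]
        table.iloc[0, 0] = 0  # some absences
        table.iloc[3, 2] = 0
        bm = assembly.beta_mntd(table, tree, abundance_weighted=weighted)
        oracle = brute_force_betamntd(table, tree, weighted=weighted)
        np.testing.assert_allclose(np.asarray(bm.data), oracle, atol=1e-12)

    def test_empty_sample_rejected(self, toy_tree):
        table = pd.DataFrame({"s1": [1, 1, 1], "s2": [0, 0, 0]}, index=["A", "B", "C"])
        with pytest.raises(ValueError, match="empty"):
            assembly.beta_mntd(table, toy_tree)


class TestBetaNti:
    def test_identical_communities_degenerate_flag(self, toy_tree):
        table = pd.DataFrame({"s1": [2, 1, 3], "s2": [2, 1, 3]}, index=["A", "B", "C"])
        res = assembly.beta_nti(table, toy_tree, assembly.NullModelConfig(n_null=49, seed=0))
        assert res.values.loc["s1", "s2"] == 0.0
        assert bool(res.degenerate.loc["s1", "s2"])

    def test_star_tree_every_shuffle_equivalent(self):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))
        table = pd.DataFrame(
            {"s1": [4, 1, 0, 0], "s2": [0, 0, 3, 2]}, index=["A", "B", "C", "D"]
        )
        res = assembly.beta_nti(table, star, assembly.NullModelConfig(n_null=49, seed=1))
        assert bool(res.degenerate.loc["s1", "s2"])
        assert res.values.loc["s1", "s2"] == 0.0

    def test_invariant_to_taxon_relabeling(self, rng):
        tree = synthdata.simulate_tree(8, seed=2)
        table = random_count_table(rng, n_taxa=8, n_samples=4, depth=100)
        table.index = [f"OTU_{i + 1}" for i in range(8)]
        cfg = assembly.NullModelConfig(n_null=99, seed=3)
        res1 = assembly.beta_nti(table, tree, cfg)
        # consistent renaming of rows and tips
        mapping = {f"OTU_{i + 1}": f"TAX_{i + 1}" for i in range(8)}
        table2 = table.rename(index=mapping)
        tree2 = tree.copy()
        for tip in tree2.tips():
            tip.name = mapping[tip.name]
        res2 = assembly.beta_nti(table2, tree2, cfg)
        np.testing.assert_allclose(
            res1.values.to_numpy(), res2.values.to_numpy(), atol=1e-10
        )


class TestRaupCrick:
    def test_identical_diverse_samples_strongly_negative(self, rng):
        base = rng.integers(1, 50, size=40)
        table = pd.DataFrame(
            {
                "s1": base,
                "s2": base,
                "s3": rng.integers(0, 50, 40),
                "s4": rng.integers(0, 50, 40),
            },
            index=[f"t{i}" for i in range(40)],
        )
        rc = assembly.raup_crick_bray(table, assembly.NullModelConfig(n_null=999, seed=0))
        assert rc.loc["s1", "s2"] <= -0.9

    def test_bounded_in_unit_interval(self, rng):
        for k in range(10):
            table = random_count_table(rng, n_taxa=15, n_samples=4, depth=80)
            rc = assembly.raup_crick_bray(
                table, assembly.NullModelConfig(n_null=49, seed=k)
            )
            assert (rc.to_numpy() <= 1.0).all() and (rc.to_numpy() >= -1.0).all()
            assert np.allclose(rc.to_numpy(), rc.to_numpy().T)

    def test_non_integer_counts_rejected(self, toy_tree):
        table = pd.DataFrame({"s1": [1.5, 1.0], "s2": [2.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="integer"):
            assembly.raup_crick_bray(table)


class TestPartition:
    def _matrices(self, bnti_vals, rc_vals):
        ids = [f"s{i}" for i in range(4)]
        iu = np.triu_indices(4, 1)
        b = np.zeros((4, 4))
        r = np.zeros((4, 4))
        b[iu] = bnti_vals
        r[iu] = rc_vals
        b += b.T
        r += r.T
        return (
            pd.DataFrame(b, index=ids, columns=ids),
            pd.DataFrame(r, index=ids, columns=ids),
        )

    def test_threshold_rules_on_hand_built_pairs(self):
        """Six pairs hitting each classification rule exactly once."""
        bnti, rc = self._matrices(
            [2.5, -2.5, 1.0, 0.0, 1.5, -1.9],
            [0.0, 0.0, -0.96, 0.0, 0.97, 0.5],
        )
        part = assembly.partition_processes(bnti, rc)
        assert part.variable_selection == pytest.approx(1 / 6)
        assert part.homogeneous_selection == pytest.approx(1 / 6)
        assert part.homogenizing_dispersal == pytest.approx(1 / 6)
        assert part.dispersal_limitation == pytest.approx(1 / 6)
        assert part.drift == pytest.approx(2 / 6)

    def test_fractions_total_one_and_split_consistent(self, rng):
        for _ in range(20):
            bnti, rc = self._matrices(rng.normal(0, 3, 6), rng.uniform(-1, 1, 6))
            p = assembly.partition_processes(bnti, rc)
            total = sum(getattr(p, name) for name in assembly.PROCESSES)
            assert total == pytest.approx(1.0, abs=1e-12)
            assert p.deterministic + p.stochastic == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_pair_sets_rejected(self):
        bnti, rc = self._matrices(np.zeros(6), np.zeros(6))
        rc = rc.rename(index={"s0": "zz"}, columns={"s0": "zz"})
        with pytest.raises(AlignmentError):
            assembly.partition_processes(bnti, rc)


class TestPairwiseRegression:
    def test_identity_slope_one(self):
        ids = list("abcd")
        v = pd.Series([0.0, 1.0, 2.0, 4.0], index=ids)
        pairs = np.abs(v.to_numpy()[:, None] - v.to_numpy()[None, :])
        y = pd.DataFrame(pairs, index=ids, columns=ids)
        res = assembly.pairwise_regression(v, y)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols_on_toy_pairs(self):
        x = np.array([0.5, 1.0, 2.0, 3.5])
        y = np.array([0.2, 0.7, 1.1, 2.0])
        res = assembly.pairwise_regression(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert res.slope == pytest.approx(sxy / sxx)
        assert res.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean())

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            assembly.pairwise_regression(np.ones(5), np.arange(5.0))

    def test_slope_t_test_calibrated_under_null(self, rng):
        """With truly independent (x, y) pairs the t-test rejects ~5%."""
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            res = assembly.pairwise_regression(x, y)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09
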