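import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from idicss.io import GeneExpressionMatrix, MutationMatrix
from idicss.profile import (
    IDICProfile,
    blend_idic,
    consensus_cluster,
    driver_ic_association,
    mutation_impact,
    signature_score,
    zscore_rows,
)


def _frame(values, index, columns):
    return pd.DataFrame(values, index=index, columns=columns)


class TestDriverIcAssociation:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        n = 150
        samples = [f"s{i}" for i in range(n)]
        carrier = rng.random(n) < 0.3
        W = _frame(rng.normal(size=(3, n)), ["IC1", "IC2", "IC3"], samples)
        W.loc["IC2"] += 2.0 * carrier  # +2 SD shift in carriers
        mut = MutationMatrix(_frame([carrier.astype(int)], ["BRAF"], samples))
        table = driver_ic_association(W, mut, ["BRAF"], min_mutated=5)
        row = table.set_index(["gene", "component"]).loc[("BRAF", "IC2")]
        assert row["q"] < 0.01
        assert row["direction"] == "+"
        other = table.set_index(["gene", "component"]).loc[("BRAF", "IC1")]
        assert other["p"] > 0.01

    def test_rare_gene_skipped(self):
        samples = [f"s{i}" for i in range(20)]
        W = _frame(np.random.default_rng(1).normal(size=(1, 20)), ["IC1"], samples)
        mut = MutationMatrix(_frame([[0] * 20], ["NEVER"], samples))
        table = driver_ic_association(W, mut, ["NEVER"], min_mutated=5)
        assert len(table) == 0

    def test_identical_groups_null(self):
        samples = [f"s{i}" for i in range(12)]
        w = np.concatenate([np.arange(1.0, 7.0), np.arange(1.0, 7.0)])
        W = _frame([w], ["IC1"], samples)
        carrier = np.array([1] * 6 + [0] * 6)
        mut = MutationMatrix(_frame([carrier], ["G"], samples))
        table = driver_ic_association(W, mut, ["G"], min_mutated=2)
        assert table.iloc[0]["effect"] == pytest.approx(0.0)
        assert table.iloc[0]["p"] == pytest.approx(1.0)


class TestMutationImpact:
    def setup_method(self):
        self.genes = ["g1", "g2", "g3"]
        self.samples = ["s1", "s2", "s3"]
        self.S = _frame(
            [[1.0, -2.0], [0.5, 0.25], [3.0, 1.0]], self.genes, ["IC1", "IC2"]
        )

    def test_no_mutations_zero_impact(self):
        mut = MutationMatrix(_frame(np.zeros((3, 3), int), self.genes, self.samples))
        impact = mutation_impact(self.S, mut, set(self.genes), ["IC1", "IC2"])
        np.testing.assert_allclose(impact.to_numpy(), 0.0)

    def test_single_mutated_gene_equals_loading_row(self):
        mut_vals = np.zeros((3, 3), int)
        mut_vals[0, 1] = 1  # g1 mutated in s2 only
        mut = MutationMatrix(_frame(mut_vals, self.genes, self.samples))
        genes = {"g1"}
        # raw (pre-z-score) impact: recompute by disabling z via direct sum
        raw = self.S.loc[["g1"]].to_numpy().T @ mut.data.loc[["g1"]].to_numpy()
        np.testing.assert_allclose(raw[:, 1], self.S.loc["g1"].to_numpy())
        np.testing.assert_allclose(raw[:, [0, 2]], 0.0)
        # z-scored output is the z-score of that raw pattern
        impact = mutation_impact(self.S, mut, genes, ["IC1", "IC2"])
        expected = zscore_rows(pd.DataFrame(raw, index=["IC1", "IC2"], columns=self.samples))
        pd.testing.assert_frame_equal(impact, expected)

    def test_identical_mutation_profiles_identical_columns(self):
        mut_vals = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0]])
        mut = MutationMatrix(_frame(mut_vals, self.genes, self.samples))
        impact = mutation_impact(self.S, mut, set(self.genes), ["IC1", "IC2"])
        np.testing.assert_allclose(impact["s1"], impact["s2"])

    def test_disjoint_gene_set_rejected(self):
        mut = MutationMatrix(_frame(np.zeros((3, 3), int), self.genes, self.samples))
        with pytest.raises(ValueError):
            mutation_impact(self.S, mut, {"nope"}, ["IC1"])


class TestBlendIdic:
    def setup_method(self):
        idx, cols = ["IC1", "IC2"], ["s1", "s2", "s3"]
        rng = np.random.default_rng(2)
        self.W = _frame(rng.normal(size=(2, 3)), idx, cols)
        self.D = _frame(rng.normal(size=(2, 3)), idx, cols)
        self.I = _frame(rng.normal(size=(2, 3)), idx, cols)

    def test_lambda_one_ignores_immune_impact(self):
        a = blend_idic(self.W, self.D, self.I, 1.0)
        b = blend_idic(self.W, self.D, self.I * 57.0, 1.0)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_zero_impacts_identity(self):
        zero = self.D * 0.0
        out = blend_idic(self.W, zero, zero, 0.7)
        pd.testing.assert_frame_equal(out.data, self.W)

    def test_scalar_arithmetic(self):
        one = _frame([[1.0]], ["IC1"], ["s1"])
        out = blend_idic(one * 0.1, one * 1.0, one * -1.0, 0.7)
        assert out.data.iloc[0, 0] == pytest.approx(0.1 + 0.7 - 0.3)

    def test_affine_in_lambda_with_slope_d_minus_i(self):
        lams = np.linspace(0, 1, 5)
        outs = [blend_idic(self.W, self.D, self.I, lam).data for lam in lams]
        slope = (outs[-1] - outs[0]) / (lams[-1] - lams[0])
        pd.testing.assert_frame_equal(slope, self.D - self.I)
        mid = outs[0] + 0.5 * (self.D - self.I)
        pd.testing.assert_frame_equal(outs[2], mid)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            blend_idic(self.W, self.D.iloc[:, :2], self.I, 0.5)

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            blend_idic(self.W, self.D, self.I, 1.5)


class TestSignatureScore:
    def test_singleton_set_is_z_profile(self):
        rng = np.random.default_rng(3)
        expr = GeneExpressionMatrix(
            _frame(rng.normal(size=(3, 8)), ["a", "b", "c"], [f"s{i}" for i in range(8)])
        )
        score = signature_score(expr, {"b"})
        expected = zscore_rows(expr.data.loc[["b"]]).iloc[0]
        pd.testing.assert_series_equal(score, expected, check_names=False)

    def test_planted_hot_half_detected(self):
        from idicss.profile import rank_sum_test

        rng = np.random.default_rng(4)
        n = 60
        base = rng.normal(size=(20, n))
        base[:10, : n // 2] += 1.0  # immune-hot first half on set genes
        expr = GeneExpressionMatrix(
            _frame(base, [f"g{i}" for i in range(20)], [f"s{i}" for i in range(n)])
        )
        score = signature_score(expr, {f"g{i}" for i in range(10)})
        p, _ = rank_sum_test(score[: n // 2], score[n // 2 :])
        assert p < 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        data = _frame(rng.normal(size=(4, 10)), list("abcd"), [f"s{i}" for i in range(10)])
        expr = GeneExpressionMatrix(data)
        rescaled = GeneExpressionMatrix(data.mul([2, 3, 4, 5], axis=0).add([10, -3, 0, 7], axis=0))
        s1 = signature_score(expr, {"a", "c"})
        s2 = signature_score(rescaled, {"a", "c"})
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_empty_intersection_rejected(self):
        expr = GeneExpressionMatrix(_frame([[1.0, 2.0]], ["a"], ["s1", "s2"]))
        with pytest.raises(ValueError):
            signature_score(expr, {"zz"})


def blob_profile(seed=0, n_per=40, sep=6.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(3, n_per))
    b = rng.normal(sep, 1.0, size=(3, n_per))
    data = np.concatenate([a, b], axis=1)
    samples = [f"s{i}" for i in range(2 * n_per)]
    truth = np.array([0] * n_per + [1] * n_per)
    return IDICProfile(_frame(data, ["IC1", "IC2", "IC3"], samples), 0.7), truth


class TestConsensusCluster:
    def test_separated_blobs_recovered(self):
        profile, truth = blob_profile(seed=6)
        sub = consensus_cluster(profile, k=2, n_resample=100, seed=6)
        ari = adjusted_rand_score(truth, sub.labels.to_numpy())
        assert ari > 0.9
        assert sub.pac < 0.1

    def test_duplicated_samples_get_same_label(self):
        profile, _ = blob_profile(seed=7, n_per=15)
        doubled = IDICProfile(
            pd.concat(
                [profile.data, profile.data.add_suffix("_dup", axis=1)], axis=1
            ),
            0.7,
        )
        sub = consensus_cluster(doubled, k=2, n_resample=100, seed=7)
        for s in profile.samples:
            assert sub.labels[s] == sub.labels[s + "_dup"]

    def test_deterministic_given_seed(self):
        profile, _ = blob_profile(seed=8)
        a = consensus_cluster(profile, k=2, n_resample=50, seed=3)
        b = consensus_cluster(profile, k=2, n_resample=50, seed=3)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_k_below_two_rejected(self):
        profile, _ = blob_profile(seed=9)
        with pytest.raises(ValueError, match="k"):
            consensus_cluster(profile, k=1)

    def test_cluster_a_is_immune_cold(self):
        # clusterA must be the group with the lower immune signature score
        profile, truth = blob_profile(seed=10)
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(12)]
        data = rng.normal(size=(12, len(profile.samples)))
        data[:6, truth == 1] += 2.0  # group 1 is immune-hot
        expr = GeneExpressionMatrix(_frame(data, genes, profile.samples))
        from idicss.io import GeneSetCollection

        sets = GeneSetCollection({"IMM": frozenset(genes[:6])})
        sub = consensus_cluster(
            profile, k=2, n_resample=100, seed=10, expression=expr, immune_sets=sets
        )
        hot = [s for s, t in zip(profile.samples, truth) if t == 1]
        assert (sub.labels[hot] == "clusterB").mean() > 0.9
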