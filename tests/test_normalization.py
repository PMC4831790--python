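import numpy as np
import pandas as pd
import pytest

import tumorhet as th

from conftest import make_count_matrix


def brute_force_m(logx: np.ndarray) -> np.ndarray:
    """Definitional geNorm M: explicit double loop over gene pairs."""
    g, _ = logx.shape
    m = np.zeros(g)
    for j in range(g):
        sds = []
        for k in range(g):
            if k == j:
                continue
            sds.append(np.std(logx[j] - logx[k], ddof=1))
        m[j] = np.mean(sds)
    return m


class TestGenormStability:
    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(10, 1000, size=(5, 6))
        df = pd.DataFrame(x, index=list("abcde"))
        ranking = th.genorm_stability(df, mode="single_pass")
        expected = brute_force_m(np.log2(x))
        np.testing.assert_allclose(
            ranking.m_values.to_numpy(), expected, atol=1e-10
        )

    def test_proportional_pair_and_noisy_third(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(100, 200, size=8)
        noisy = rng.uniform(50, 500, size=8)
        df = pd.DataFrame(
            [base, 3.0 * base, noisy], index=["g1", "g2", "g3"]
        )
        ranking = th.genorm_stability(df, mode="single_pass")
        # the proportional pair has zero mutual ratio-SD, so their M comes
        # entirely from the ratio to the noisy gene
        sd13 = np.std(np.log2(base) - np.log2(noisy), ddof=1)
        assert ranking.m_values["g1"] == pytest.approx(sd13 / 2)
        assert ranking.m_values["g2"] == pytest.approx(sd13 / 2)
        assert ranking.m_values.idxmax() == "g3"

    def test_identical_genes_all_zero_m(self):
        df = pd.DataFrame(np.full((4, 5), 250.0), index=list("abcd"))
        ranking = th.genorm_stability(df)
        assert (ranking.m_values == 0).all()

    def test_invariant_to_per_sample_scaling(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(10, 1000, size=(5, 6))
        df = pd.DataFrame(x, index=list("abcde"))
        scaled = df.copy()
        scaled.iloc[:, 2] *= 7.5  # depth change in one sample
        r1 = th.genorm_stability(df)
        r2 = th.genorm_stability(scaled)
        np.testing.assert_allclose(
            r1.m_values.to_numpy(), r2.m_values.to_numpy(), atol=1e-12
        )
        assert r1.removal_order == r2.removal_order

    def test_rejects_nonpositive_and_tiny_inputs(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 0.0], [1, 1]],
                          index=list("abc"))
        with pytest.raises(ValueError, match="non-positive"):
            th.genorm_stability(df)
        with pytest.raises(ValueError, match="3 candidate"):
            th.genorm_stability(df.iloc[:2])


class TestSelectReferenceGenes:
    def test_keep_all_is_identity(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.uniform(10, 100, (5, 6)), index=list("abcde"))
        ranking = th.genorm_stability(df)
        assert set(th.select_reference_genes(ranking, 5)) == set("abcde")

    def test_planted_unstable_candidate_excluded_first(self):
        rng = np.random.default_rng(15)
        base = rng.uniform(100, 200, size=10)
        rows = {f"g{i}": base * rng.uniform(0.95, 1.05, 10) for i in range(6)}
        rows["bad"] = rng.uniform(10, 2000, size=10)  # planted high variance
        df = pd.DataFrame(rows).T
        ranking = th.genorm_stability(df)
        assert ranking.removal_order[0] == "bad"
        kept = th.select_reference_genes(ranking, 6)
        assert "bad" not in kept

    def test_n_keep_too_large_errors(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(rng.uniform(10, 100, (4, 5)), index=list("abcd"))
        ranking = th.genorm_stability(df)
        with pytest.raises(ValueError):
            th.select_reference_genes(ranking, 5)

    def test_stable_under_candidate_permutation(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(rng.uniform(10, 1000, (6, 8)),
                          index=[f"g{i}" for i in range(6)])
        r1 = th.genorm_stability(df)
        perm = df.sample(frac=1.0, random_state=3)
        r2 = th.genorm_stability(perm)
        assert th.select_reference_genes(r1, 4) == th.select_reference_genes(r2, 4)


class TestNormalize:
    def _matrix_with_depth(self, depths):
        rng = np.random.default_rng(18)
        base = rng.integers(8, 500, size=(6, len(depths))) * 4
        base = base[:, [0]] * np.ones((1, len(depths)), dtype=int)
        counts = (base * np.asarray(depths)[None, :]).astype(int)
        genes = [f"g{i}" for i in range(4)] + ["r1", "r2"]
        cm = th.CountMatrix(
            pd.DataFrame(counts, index=genes,
                         columns=[f"s{i}" for i in range(len(depths))]),
            pd.Series(["endogenous"] * 4 + ["reference"] * 2, index=genes),
        )
        return cm

    def test_identical_samples_unit_factors(self):
        cm = self._matrix_with_depth([1, 1, 1])
        from tumorhet.normalization import scale_factors
        f = scale_factors(cm, ["r1", "r2"])
        np.testing.assert_allclose(f.to_numpy(), 1.0)

    def test_pure_depth_effect_removed(self):
        cm = self._matrix_with_depth([1, 2])
        from tumorhet.normalization import scale_factors
        f = scale_factors(cm, ["r1", "r2"])
        assert f["s1"] == pytest.approx(f["s0"] / 2)
        normed = th.normalize(cm, ["r1", "r2"])
        np.testing.assert_allclose(
            normed.values["s0"], normed.values["s1"], rtol=1e-12
        )

    def test_known_depth_multipliers_recovered(self):
        depths = [1, 2, 0.5, 4]
        cm = self._matrix_with_depth(depths)
        from tumorhet.normalization import scale_factors
        f = scale_factors(cm, ["r1", "r2"]).to_numpy()
        expected = 1.0 / np.asarray(depths)
        ratio = f / expected
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_idempotent(self):
        # a normalized matrix renormalizes with unit factors
        cm = self._matrix_with_depth([1, 3, 0.5])
        normed = th.normalize(cm, ["r1", "r2"])
        gm = np.exp(np.log(normed.values.loc[["r1", "r2"]]).mean(axis=0))
        factors2 = gm.mean() / gm
        np.testing.assert_allclose(factors2.to_numpy(), 1.0, atol=1e-12)

    def test_zero_reference_count_warns_then_errors(self):
        genes = ["g0", "r1", "r2"]
        counts = pd.DataFrame(
            [[5, 6], [0, 10], [10, 10]], index=genes, columns=["s0", "s1"]
        )
        cm = th.CountMatrix(
            counts,
            pd.Series(["endogenous", "reference", "reference"], index=genes),
        )
        with pytest.warns(UserWarning, match="pseudocount"):
            th.normalize(cm, ["r1", "r2"], pseudocount=1.0)
        with pytest.raises(ValueError):
            th.normalize(cm, ["r1", "r2"], pseudocount=0.0)


class TestLogTransform:
    @pytest.mark.parametrize(
        "value,pseudo,expected", [(4.0, 0.0, 2.0), (0.0, 1.0, 0.0)]
    )
    def test_known_values(self, value, pseudo, expected):
        m = th.ExpressionMatrix(pd.DataFrame([[value]]))
        out = th.log_transform(m, pseudo)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.is_log2

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(19)
        vals = pd.DataFrame(rng.uniform(0, 1000, size=(5, 4)))
        out = th.log_transform(th.ExpressionMatrix(vals), 1.0)
        back = 2.0 ** out.values - 1.0
        np.testing.assert_allclose(back.to_numpy(), vals.to_numpy(),
                                   atol=1e-12, rtol=1e-12)

    def test_nonpositive_rejected(self):
        m = th.ExpressionMatrix(pd.DataFrame([[-2.0]]))
        with pytest.raises(ValueError):
            th.log_transform(m, 1.0)
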