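import numpy as np
import pandas as pd
import pytest

from icisig.cohort_io import ExpressionMatrix
from icisig.signatures import (
    Signature,
    combination_classify,
    derive_proliferation_signature,
    derive_stroma_signature,
    fit_combination_threshold,
    geometric_mean_score,
    mean_normalize,
)

from conftest import make_de_table


def fpkm_matrix(values, genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), "fpkm")


class TestMeanNormalize:
    def test_cohort_mean_is_one(self):
        rng = np.random.default_rng(0)
        m = fpkm_matrix(rng.gamma(2, 50, size=(20, 6)))
        norm = mean_normalize(m)
        np.testing.assert_allclose(norm.data.mean(axis=1), 1.0)

    def test_constant_gene_normalizes_to_one(self):
        m = fpkm_matrix([[7.0, 7.0, 7.0]])
        np.testing.assert_allclose(mean_normalize(m).values, 1.0)

    def test_two_sample_arithmetic(self):
        m = fpkm_matrix([[4.0, 8.0]])
        norm = mean_normalize(m)
        np.testing.assert_allclose(
            norm.values[0], [2 / 3, 4 / 3], atol=1e-3
        )  # eps = 0.01 is negligible here

    def test_cohort_subset_defines_the_mean(self):
        m = fpkm_matrix([[4.0, 8.0, 100.0]])
        norm = mean_normalize(m, cohort_samples=["s0", "s1"])
        np.testing.assert_allclose(norm.values[0][:2], [2 / 3, 4 / 3], atol=1e-3)

    def test_empty_cohort_rejected(self):
        m = fpkm_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="cohort"):
            mean_normalize(m, cohort_samples=[])


class TestDeriveStromaSignature:
    def test_top_ten_by_p_value(self):
        rows = {f"caf{i:02d}": (0.5 + 0.1 * i, 0.001 * (i + 1)) for i in range(12)}
        de = make_de_table(rows)
        sig = derive_stroma_signature(de, list(rows))
        assert len(sig) == 10
        assert sig.gene_ids == [f"caf{i:02d}" for i in range(10)]
        assert sig.direction == "up_in_responders"

    def test_nonsignificant_marker_excluded(self):
        de = make_de_table({"big_fc": (2.0, 0.2), "ok": (0.5, 0.01)})
        with pytest.warns(UserWarning):
            sig = derive_stroma_signature(de, ["big_fc", "ok"], k=10)
        assert sig.gene_ids == ["ok"]

    def test_downregulated_marker_excluded(self):
        de = make_de_table({"down": (-2.0, 0.001), "up": (0.5, 0.01)})
        with pytest.warns(UserWarning):
            sig = derive_stroma_signature(de, ["down", "up"])
        assert sig.gene_ids == ["up"]

    def test_fewer_candidates_than_k_warns(self):
        rows = {f"c{i}": (1.0, 0.01) for i in range(6)}
        de = make_de_table(rows)
        with pytest.warns(UserWarning, match="6"):
            sig = derive_stroma_signature(de, list(rows), k=10)
        assert len(sig) == 6

    def test_zero_candidates_error(self):
        de = make_de_table({"c": (1.0, 0.5)})
        with pytest.raises(ValueError, match="no CAF marker"):
            derive_stroma_signature(de, ["c"])

    def test_tie_break_by_abs_log2fc_then_gene_id(self):
        de = make_de_table(
            {"b": (1.0, 0.01), "a": (1.0, 0.01), "c": (2.0, 0.01)}
        )
        sig = derive_stroma_signature(de, ["a", "b", "c"], k=3)
        assert sig.gene_ids == ["c", "a", "b"]


class TestDeriveProliferationSignature:
    def test_shared_gene_appears_once(self):
        de = make_de_table({"shared": (-1.5, 0.01), "g2m_only": (-2.0, 0.01)})
        sig = derive_proliferation_signature(
            de, ["shared", "g2m_only"], ["shared"]
        )
        assert sorted(sig.gene_ids) == ["g2m_only", "shared"]
        assert sig.direction == "down_in_responders"

    def test_threshold_inclusive_at_minus_one(self):
        de = make_de_table({"exact": (-1.0, 0.01), "weak": (-0.99, 0.01)})
        sig = derive_proliferation_signature(de, ["exact", "weak"], [])
        assert sig.gene_ids == ["exact"]

    def test_hand_filtering(self):
        de = make_de_table(
            {
                "d1": (-1.2, 0.01),
                "d2": (-3.0, 0.01),
                "d3": (-1.0, 0.01),
                "w1": (-0.5, 0.01),
                "u1": (1.5, 0.01),  # up-regulated: wrong direction
            }
        )
        sig = derive_proliferation_signature(de, ["d1", "d2", "w1"], ["d3", "u1"])
        assert sorted(sig.gene_ids) == ["d1", "d2", "d3"]

    def test_empty_result_error(self):
        de = make_de_table({"w": (-0.5, 0.01)})
        with pytest.raises(ValueError, match="no cell-cycle gene"):
            derive_proliferation_signature(de, ["w"], [])


def norm_matrix(values, **kw):
    m = fpkm_matrix(values, **kw)
    return ExpressionMatrix(m.data, "normalized")


class TestGeometricMeanScore:
    def test_reciprocal_pair_scores_one(self):
        m = norm_matrix([[0.5], [2.0]])
        sig = Signature("s", ["g0", "g1"], "up_in_responders")
        assert geometric_mean_score(m, sig)["s0"] == pytest.approx(1.0)

    def test_powers_of_two(self):
        m = norm_matrix([[1.0], [2.0], [4.0]])
        sig = Signature("s", ["g0", "g1", "g2"], "up_in_responders")
        assert geometric_mean_score(m, sig)["s0"] == pytest.approx(2.0)

    def test_matches_product_root_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2.0, 1.0, size=(7, 5)) + 0.01
        m = norm_matrix(vals)
        sig = Signature("s", [f"g{i}" for i in range(7)], "up_in_responders")
        scores = geometric_mean_score(m, sig)
        oracle = np.prod(vals, axis=0) ** (1 / 7)
        np.testing.assert_allclose(scores.to_numpy(), oracle, atol=1e-10)

    def test_missing_genes_listed(self):
        m = norm_matrix([[1.0]])
        sig = Signature("s", ["g0", "absent"], "up_in_responders")
        with pytest.raises(ValueError, match="absent"):
            geometric_mean_score(m, sig)


class TestScaleInvariance:
    def test_gene_rescaling_leaves_scores_unchanged(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2, 50, size=(10, 6))
        sig = Signature("s", [f"g{i}" for i in range(4)], "up_in_responders")
        base = geometric_mean_score(mean_normalize(fpkm_matrix(vals)), sig)
        scaled_vals = vals * rng.uniform(0.5, 20, size=(10, 1))
        scaled = geometric_mean_score(
            mean_normalize(fpkm_matrix(scaled_vals)), sig
        )
        # eps breaks exact invariance at tiny FPKM; these values are O(100)
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(), rtol=1e-3)

    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2, 50, size=(10, 6))
        sig = Signature("s", [f"g{i}" for i in range(4)], "up_in_responders")
        m = fpkm_matrix(vals)
        base = geometric_mean_score(mean_normalize(m), sig)
        perm = ["s3", "s1", "s5", "s0", "s2", "s4"]
        permuted = ExpressionMatrix(m.data[perm], "fpkm")
        out = geometric_mean_score(mean_normalize(permuted), sig)
        np.testing.assert_allclose(out.to_numpy(), base[perm].to_numpy())


def brute_force_best_threshold(scores, truth):
    """Exhaustive sweep over candidate thresholds, maximizing Youden's J."""
    best = None
    for t in sorted(set(scores)):
        pred = np.asarray(scores) >= t
        truth = np.asarray(truth)
        sens = (pred & truth).sum() / truth.sum()
        spec = (~pred & ~truth).sum() / (~truth).sum()
        j = sens + spec - 1
        if best is None or j > best[1]:
            best = (t, j)
    return best


class TestCombinationClassify:
    def scores_frame(self, stroma, prolif, index=None):
        index = index or [f"s{i}" for i in range(len(stroma))]
        return pd.DataFrame(
            {"stroma_score": stroma, "proliferation_score": prolif}, index=index
        )

    def test_fixed_threshold_rule(self):
        df = self.scores_frame([2.0, 0.5], [0.5, 2.0])
        out = combination_classify(df, threshold=0.0)
        assert list(out["predicted_label"]) == ["responder", "non-responder"]

    def test_separable_training_is_perfect(self):
        df = self.scores_frame([2, 3, 0.5, 0.4], [0.5, 0.3, 2, 3])
        labels = pd.Series(
            ["DR", "DR", "NR", "NR"], index=df.index
        )
        out = combination_classify(df, training_labels=labels)
        pred = out["predicted_label"] == "responder"
        assert pred.tolist() == [True, True, False, False]

    def test_matches_brute_force_sweep_with_overlap(self):
        # 4 + 4 cohort with one overlapping point
        stroma = [3.0, 2.5, 2.0, 0.6, 0.5, 0.6, 0.7, 2.0]
        prolif = [0.4, 0.5, 0.6, 0.9, 2.0, 2.2, 1.8, 0.6]
        truth = [True, True, True, True, False, False, False, False]
        df = self.scores_frame(stroma, prolif)
        labels = pd.Series(truth, index=df.index)
        out = combination_classify(df, training_labels=labels)
        comb = out["combination_score"].to_numpy()
        # sweeping the observed scores enumerates every achievable
        # prediction pattern, so the oracle's best J is the global optimum
        _, j_oracle = brute_force_best_threshold(comb, truth)
        pred = out["predicted_label"] == "responder"
        tp = (pred & labels).sum()
        tn = (~pred & ~labels).sum()
        j_ours = tp / 4 + tn / 4 - 1
        assert j_ours == pytest.approx(j_oracle)

    def test_separable_margin_cut_at_midpoint(self):
        comb = [1.0, 2.0, -1.0, -2.0]
        truth = [True, True, False, False]
        # every cut in (-1, 1] separates perfectly; the midpoint candidate
        # of the boundary pair (-1, 1) is the smallest that achieves J = 1
        assert fit_combination_threshold(comb, truth) == 0.0

    def test_two_threshold_method(self):
        df = self.scores_frame([2.0, 2.0, 0.5], [0.5, 2.0, 0.5])
        out = combination_classify(
            df, method="two_threshold", two_threshold=(1.0, 1.0)
        )
        assert list(out["predicted_label"]) == [
            "responder",
            "non-responder",
            "non-responder",
        ]

    def test_requires_threshold_or_labels(self):
        df = self.scores_frame([1.0], [1.0])
        with pytest.raises(ValueError, match="threshold"):
            combination_classify(df)
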