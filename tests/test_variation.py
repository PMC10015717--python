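import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from devstab import (
    ExpressionMatrix,
    pairwise_variation,
    running_median_correction,
)
from devstab.pairing import PairSet


def _matrix(values, samples):
    idx = pd.Index([f"g{i}" for i in range(np.asarray(values).shape[0])],
                   name="gene_id")
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=samples),
                            units="log10")


def _table(mean_expression, raw_variation):
    n = len(mean_expression)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "mean_expression": mean_expression,
            "raw_variation": raw_variation,
        }
    ).set_index("gene_id", drop=False)


class TestPairwiseVariation:
    def test_identical_samples_give_zero(self):
        m = _matrix([[1.0, 1.0], [2.5, 2.5]], ["a", "b"])
        t = pairwise_variation(m, PairSet("sibling", "15", [("a", "b")]))
        assert (t["raw_variation"] == 0).all()

    def test_single_pair_absolute_difference(self):
        m = _matrix([[1.0, 3.0]], ["a", "b"])
        t = pairwise_variation(m, PairSet("sibling", "15", [("a", "b")]))
        assert t["raw_variation"].iloc[0] == pytest.approx(2.0)

    def test_all_pairs_average_hand_computed(self):
        # values 0, 1, 3: pairwise diffs 1, 3, 2 -> mean 2.0
        m = _matrix([[0.0, 1.0, 3.0]], ["a", "b", "c"])
        ps = PairSet("hybrid_all_pairs", "15", [("a", "b"), ("a", "c"), ("b", "c")])
        t = pairwise_variation(m, ps)
        assert t["raw_variation"].iloc[0] == pytest.approx(2.0)
        assert t["mean_expression"].iloc[0] == pytest.approx(4.0 / 3.0)

    def test_pair_order_and_relabeling_invariance(self, rng):
        v = rng.gamma(2, 1, size=(10, 4))
        m = _matrix(v, ["a", "b", "c", "d"])
        t1 = pairwise_variation(m, PairSet("sibling", "15", [("a", "b"), ("c", "d")]))
        t2 = pairwise_variation(m, PairSet("sibling", "15", [("d", "c"), ("b", "a")]))
        np.testing.assert_allclose(t1["raw_variation"], t2["raw_variation"])

    def test_translation_invariance_per_gene(self, rng):
        v = rng.gamma(2, 1, size=(5, 4))
        m1 = _matrix(v, list("abcd"))
        m2 = _matrix(v + 3.0, list("abcd"))
        ps = PairSet("sibling", "15", [("a", "b"), ("c", "d")])
        np.testing.assert_allclose(
            pairwise_variation(m1, ps)["raw_variation"],
            pairwise_variation(m2, ps)["raw_variation"],
        )


class TestRunningMedianCorrection:
    def test_constant_raw_variation_corrects_to_zero(self):
        t = _table(np.linspace(0, 3, 20), np.full(20, 0.7))
        out = running_median_correction(t, window=5)
        np.testing.assert_allclose(out["corrected_variation"], 0.0, atol=1e-15)

    def test_five_genes_window_three_hand_case(self):
        # raw by expression rank: 1..5; interior medians equal the centre value,
        # edge half-width shrinks to zero -> all corrections are zero
        t = _table([0.1, 0.2, 0.3, 0.4, 0.5], [1.0, 2.0, 3.0, 4.0, 5.0])
        out = running_median_correction(t, window=3)
        np.testing.assert_allclose(out["corrected_variation"], 0.0)

    def test_matches_naive_oracle(self, rng):
        n, window = 400, 31
        t = _table(rng.random(n), rng.gamma(2, 1, size=n))
        out = running_median_correction(t, window=window)
        order = np.lexsort((t["gene_id"].to_numpy(), t["mean_expression"].to_numpy()))
        raw_sorted = t["raw_variation"].to_numpy()[order]
        half = (window - 1) // 2
        expected_sorted = np.empty(n)
        for r in range(n):
            h = min(half, r, n - 1 - r)
            expected_sorted[r] = raw_sorted[r] - np.median(raw_sorted[r - h:r + h + 1])
        expected = np.empty(n)
        expected[order] = expected_sorted
        np.testing.assert_allclose(out["corrected_variation"], expected, atol=1e-12)

    def test_window_shrinks_when_fewer_genes_than_window(self, rng):
        t = _table(rng.random(7), rng.random(7))
        out = running_median_correction(t, window=501)
        # every position uses the symmetric shrunken window
        mid = np.median(t["raw_variation"])
        srt = t.reset_index(drop=True).sort_values(["mean_expression", "gene_id"])
        centre_gene = srt["gene_id"].iloc[3]
        assert out.loc[centre_gene, "corrected_variation"] == pytest.approx(
            srt["raw_variation"].iloc[3] - mid
        )

    def test_preserves_gene_order_and_count(self, rng):
        t = _table(rng.random(50), rng.random(50))
        out = running_median_correction(t, window=11)
        assert list(out["gene_id"]) == list(t["gene_id"])

    @pytest.mark.parametrize("window", [4, 1, -3])
    def test_bad_window_errors(self, window):
        t = _table([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            running_median_correction(t, window=window)

    def test_decorrelates_planted_trend(self, rng):
        n = 4000
        mean_expr = rng.random(n) * 3
        raw = 0.2 + 0.5 * mean_expr + rng.gamma(2, 0.05, size=n)
        t = _table(mean_expr, raw)
        out = running_median_correction(t, window=301)
        raw_rho = spearmanr(t["raw_variation"], t["mean_expression"]).statistic
        cor_rho = spearmanr(out["corrected_variation"], out["mean_expression"]).statistic
        assert raw_rho > 0.5
        assert abs(cor_rho) < 0.05
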