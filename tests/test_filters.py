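import numpy as np
import pandas as pd
import pytest

from devstab import (
    ExpressionMatrix,
    differential_mean_filter,
    pair_differences,
    technical_error_filter,
    technical_error_values,
)
from devstab.pairing import PairSet


def _diff_frames(sib_values, tech_values, n_genes=1):
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    sib = pd.DataFrame([sib_values] * n_genes, index=idx)
    tech = pd.DataFrame([tech_values] * n_genes, index=idx)
    return sib, tech


class TestTechnicalErrorFilter:
    def test_fully_separated_gene_passes(self):
        sib, tech = _diff_frames([10.0] * 13, [0.0] * 6)
        rep = technical_error_filter(sib, tech, alpha=0.01)
        assert bool(rep["passed"].iloc[0])
        assert rep["p_value"].iloc[0] < 0.01

    def test_identical_distributions_not_passed(self):
        sib, tech = _diff_frames([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rep = technical_error_filter(sib, tech, alpha=0.01)
        assert not bool(rep["passed"].iloc[0])
        assert rep["p_value"].iloc[0] > 0.3

    def test_untestable_design_flagged_not_passed(self):
        idx = pd.Index(["g0"], name="gene_id")
        sib = pd.DataFrame([[1.0, 2.0, 3.0]], index=idx)
        tech = pd.DataFrame([[0.5]], index=idx)  # single technical value
        rep = technical_error_filter(sib, tech)
        assert not bool(rep["testable"].iloc[0])
        assert not bool(rep["passed"].iloc[0])

    def test_scaling_leaves_pvalues_unchanged(self, rng):
        idx = pd.Index([f"g{i}" for i in range(50)], name="gene_id")
        sib = pd.DataFrame(rng.gamma(2, 1, size=(50, 13)), index=idx)
        tech = pd.DataFrame(rng.gamma(2, 0.5, size=(50, 6)), index=idx)
        p1 = technical_error_filter(sib, tech)["p_value"]
        p2 = technical_error_filter(7.3 * sib, 7.3 * tech)["p_value"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_mismatched_gene_index_errors(self):
        sib = pd.DataFrame([[1.0, 2.0]], index=["gA"])
        tech = pd.DataFrame([[1.0, 2.0]], index=["gB"])
        with pytest.raises(ValueError, match="gene index"):
            technical_error_filter(sib, tech)


class TestDifferentialMeanFilter:
    def _matrix(self, values, samples):
        idx = pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id")
        return ExpressionMatrix(
            pd.DataFrame(values, index=idx, columns=samples), units="log10"
        )

    def test_identical_populations_not_passed(self, rng):
        v = rng.gamma(2, 1, size=(10, 8))
        m_a = self._matrix(v, [f"a{i}" for i in range(8)])
        m_b = self._matrix(v, [f"b{i}" for i in range(8)])
        rep = differential_mean_filter(m_a, m_b)
        assert not rep["passed"].any()

    def test_large_shift_passes(self, rng):
        v = rng.normal(1, 0.1, size=(5, 10))
        m_a = self._matrix(v, [f"a{i}" for i in range(10)])
        m_b = self._matrix(v + 5.0, [f"b{i}" for i in range(10)])
        rep = differential_mean_filter(m_a, m_b, alpha=0.01)
        assert rep["passed"].all()

    def test_alpha_one_passes_all_testable_genes(self, rng):
        v = rng.normal(1, 0.3, size=(20, 6))
        w = rng.normal(1, 0.3, size=(20, 6))
        m_a = self._matrix(v, [f"a{i}" for i in range(6)])
        m_b = self._matrix(w, [f"b{i}" for i in range(6)])
        rep = differential_mean_filter(m_a, m_b, alpha=1.0)
        assert rep.loc[rep["testable"], "passed"].all()

    def test_universe_mismatch_errors(self, rng):
        m_a = self._matrix(rng.random((3, 4)), [f"a{i}" for i in range(4)])
        m_b = self._matrix(rng.random((2, 4)), [f"b{i}" for i in range(4)])
        m_b.data.index = pd.Index(["gX", "g1"], name="gene_id")
        with pytest.raises(ValueError, match="universe mismatch"):
            differential_mean_filter(m_a, m_b)


class TestPairDifferences:
    def test_values_and_orientation(self, toy_matrix):
        ps = PairSet("hybrid_all_pairs", "15", [("s1", "s2"), ("s3", "s4")])
        diffs = pair_differences(toy_matrix, ps)
        np.testing.assert_allclose(diffs["s1|s2"], [0.0, 2.0, 0.5])
        np.testing.assert_allclose(diffs["s3|s4"], [0.0, 2.0, 1.0])

    def test_empty_pairset_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="empty PairSet"):
            pair_differences(toy_matrix, PairSet("technical", "15", []))

    def test_averaged_mode_collapses_conditions(self, toy_matrix):
        from conftest import make_metadata

        meta = make_metadata(
            [("s1", "15", "tech", None, None, "c1"),
             ("s2", "15", "tech", None, None, "c1"),
             ("s3", "15", "tech", None, None, "c2"),
             ("s4", "15", "tech", None, None, "c2")]
        )
        ps = PairSet("technical", "15", [("s1", "s2"), ("s3", "s4")])
        out = technical_error_values(toy_matrix, ps, meta, mode="averaged")
        assert list(out.columns) == ["c1", "c2"]
        np.testing.assert_allclose(out["c1"], [0.0, 2.0, 0.5])
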