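import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periput import genesets, scoring

from .conftest import random_expression
from .oracles import ssgsea_walk


def _collection(*sets):
    return genesets.GeneSetCollection(tuple(sets))


class TestLognormalize:
    def test_formula(self):
        counts = pd.DataFrame({"u": [1, 1, 2]}, index=["A", "B", "C"], dtype=float)
        out = scoring.lognormalize(counts, scale=1e4)
        np.testing.assert_allclose(
            out["u"], [np.log(2501), np.log(2501), np.log(5001)]
        )

    def test_zero_total_unit_is_zeroed(self):
        counts = pd.DataFrame({"u": [0, 0]}, index=["A", "B"])
        out = scoring.lognormalize(counts)
        assert (out["u"] == 0).all()

    def test_depth_invariance(self, rng):
        counts = pd.DataFrame(
            rng.poisson(5, size=(20, 4)).astype(float),
            index=[f"G{i}" for i in range(20)],
        )
        np.testing.assert_allclose(
            scoring.lognormalize(counts), scoring.lognormalize(counts * 2)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            scoring.lognormalize(pd.DataFrame({"u": [-1.0, 2.0]}))


class TestBulkNormalize:
    def test_per_gene_zscore(self, rng):
        expr = pd.DataFrame(rng.gamma(2, 10, size=(30, 12)))
        out = scoring.bulk_normalize(expr)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_constant_gene_maps_to_zero(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = scoring.bulk_normalize(expr)
        assert (out.iloc[0] == 0).all()

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            scoring.bulk_normalize(pd.DataFrame({"u": [1.0, 2.0]}))


class TestSsgseaHandExamples:
    """Four genes at expression [4,3,2,1]: the walk for the top gene is
    (1-0) + (1-1/3) + (1-2/3) + (1-1) = 2, and -2 for the bottom gene."""

    expr = pd.DataFrame({"u": [4.0, 3.0, 2.0, 1.0]}, index=["G1", "G2", "G3", "G4"])

    def test_top_gene_scores_two(self):
        coll = _collection(genesets.GeneSet("top", ("G1",)))
        assert scoring.ssgsea(self.expr, coll).loc["top", "u"] == pytest.approx(2.0)

    def test_bottom_gene_scores_minus_two(self):
        coll = _collection(genesets.GeneSet("bottom", ("G4",)))
        assert scoring.ssgsea(self.expr, coll).loc["bottom", "u"] == pytest.approx(-2.0)

    def test_rank_invariance_under_cubing(self):
        coll = _collection(genesets.GeneSet("top", ("G1",)))
        cubed = self.expr**3
        assert (
            scoring.ssgsea(cubed, coll).loc["top", "u"]
            == scoring.ssgsea(self.expr, coll).loc["top", "u"]
        )


class TestSsgseaProperties:
    def test_matches_bruteforce_oracle(self, rng):
        """Vectorized engine equals the loop oracle on random instances."""
        for _ in range(25):
            expr = random_expression(rng, 50, 8)
            size = int(rng.integers(3, 11))
            members = rng.choice(50, size=size, replace=False)
            coll = _collection(
                genesets.GeneSet("s", tuple(expr.index[members]))
            )
            got = scoring.ssgsea(expr, coll, alpha=0.25)
            member_mask = np.zeros(50, dtype=bool)
            member_mask[members] = True
            for j, unit in enumerate(expr.columns):
                expected = ssgsea_walk(expr[unit].to_numpy(), member_mask, 0.25)
                assert abs(got.loc["s", unit] - expected) < 1e-10

    def test_gene_order_permutation_invariance(self, rng):
        expr = random_expression(rng, 40, 5)
        coll = _collection(genesets.GeneSet("s", ("G3", "G10", "G17")))
        perm = expr.sample(frac=1.0, random_state=7)
        pd.testing.assert_frame_equal(
            scoring.ssgsea(expr, coll), scoring.ssgsea(perm, coll)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=9))
    def test_monotone_transform_leaves_scores_unchanged(self, power):
        rng = np.random.default_rng(power)
        expr = random_expression(rng, 30, 3)
        coll = _collection(genesets.GeneSet("s", ("G1", "G5", "G9")))
        base = scoring.ssgsea(expr, coll)
        transformed = scoring.ssgsea(np.exp(expr) ** power, coll)
        pd.testing.assert_frame_equal(base, transformed)

    def test_random_set_null_mean(self, rng):
        """With unweighted ECDFs (alpha=0) the walk is exactly zero-mean over
        uniformly random sets; the default rank weighting (alpha=0.25) shifts
        the null mean positive because highly expressed genes carry extra
        in-set weight — assert both behaviours."""
        g = 60
        expr = pd.DataFrame(
            {"u": rng.permutation(np.arange(1, g + 1)).astype(float)},
            index=[f"G{i}" for i in range(g)],
        )
        sets = [
            genesets.GeneSet(f"r{i}", tuple(f"G{j}" for j in rng.choice(g, 10, replace=False)))
            for i in range(1000)
        ]
        coll = genesets.GeneSetCollection(tuple(sets))
        unweighted = scoring.ssgsea(expr, coll, alpha=0.0)["u"]
        se = unweighted.std(ddof=1) / np.sqrt(len(unweighted))
        assert abs(unweighted.mean()) < 3 * se + 1e-9
        weighted = scoring.ssgsea(expr, coll, alpha=0.25)["u"]
        assert weighted.mean() > 0

    def test_all_tied_unit_scores_zero(self):
        expr = pd.DataFrame({"u": [1.0, 1.0, 1.0, 1.0]}, index=list("ABCD"))
        coll = _collection(genesets.GeneSet("s", ("A", "B")))
        assert scoring.ssgsea(expr, coll).loc["s", "u"] == 0.0

    def test_range_normalization_rescales_matrix(self, rng):
        expr = random_expression(rng, 30, 6)
        coll = _collection(
            genesets.GeneSet("a", ("G1", "G2", "G3")),
            genesets.GeneSet("b", ("G10", "G11", "G12")),
        )
        raw = scoring.ssgsea(expr, coll, normalize=False)
        norm = scoring.ssgsea(expr, coll, normalize=True)
        spread = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(norm, raw / spread)

    def test_set_covering_all_genes_rejected(self):
        expr = pd.DataFrame({"u": [2.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="covers every gene"):
            scoring.ssgsea(expr, _collection(genesets.GeneSet("s", ("A", "B"))))

    def test_set_without_matrix_genes_rejected(self):
        expr = pd.DataFrame({"u": [2.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="no genes"):
            scoring.ssgsea(expr, _collection(genesets.GeneSet("s", ("ZZZ",))))


class TestDerivedIndices:
    def _scores(self, s_in, s_loss, s_trans):
        return pd.DataFrame(
            {"u": [s_in, s_loss, s_trans]},
            index=["put_biosynthesis", "put_loss", "put_transport"],
        )

    def test_ratio_and_difference(self):
        out = scoring.derive_put_indices(self._scores(0.2, 0.3, 0.4))
        assert out.loc[scoring.EXTRACELLULAR, "u"] == pytest.approx(2.0)
        assert out.loc[scoring.ACCUMULATION, "u"] == pytest.approx(-0.1)

    def test_accumulation_example(self):
        out = scoring.derive_put_indices(self._scores(0.5, 0.3, 0.1))
        assert out.loc[scoring.ACCUMULATION, "u"] == pytest.approx(0.2)

    def test_nonpositive_sin_flagged_invalid(self):
        out = scoring.derive_put_indices(self._scores(0.0, 0.3, 0.4))
        assert np.isnan(out.loc[scoring.EXTRACELLULAR, "u"])

    def test_missing_rows_rejected(self):
        scores = pd.DataFrame({"u": [0.1]}, index=["put_biosynthesis"])
        with pytest.raises(ValueError, match="required rows"):
            scoring.derive_put_indices(scores)
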