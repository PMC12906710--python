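import numpy as np
import pandas as pd
import pytest

from periput import markers

from .oracles import auc_pair_counting


def _tiny_cohort():
    """Hand-built 8-cell cohort across two samples/subjects."""
    ann = pd.DataFrame(
        {
            "sample_id": ["S1"] * 4 + ["S2"] * 4,
            "subject_id": ["P1"] * 4 + ["P1"] * 4,
            "tissue": ["Tumor"] * 4 + ["Normal"] * 4,
            "broad_type": ["TNKILC"] * 8,
            "t_subset": ["CD8T", "CD8T", "CD4T", "NK"] * 2,
        },
        index=[f"c{i}" for i in range(8)],
    )
    counts = pd.DataFrame(
        {
            "c0": [3, 5], "c1": [0, 4], "c2": [5, 0], "c3": [0, 0],
            "c4": [1, 2], "c5": [0, 3], "c6": [2, 1], "c7": [0, 0],
        },
        index=["CXCR6", "ACTB"],
        dtype=float,
    )
    return counts, ann


class TestLabeling:
    def test_positivity_rule(self):
        counts, ann = _tiny_cohort()
        out = markers.label_cxcr6_cd8(counts, ann)
        assert out.loc["c0", "cxcr6_status"] == "pos"   # CD8T with counts
        assert out.loc["c1", "cxcr6_status"] == "neg"   # CD8T without
        assert out.loc["c2", "cxcr6_status"] == "na"    # CD4T despite counts
        assert out.loc["c3", "cxcr6_status"] == "na"    # NK

    def test_missing_cxcr6_rejected(self):
        counts, ann = _tiny_cohort()
        with pytest.raises(ValueError, match="CXCR6"):
            markers.label_cxcr6_cd8(counts.drop(index="CXCR6"), ann)


class TestPctExpressed:
    @pytest.mark.parametrize(
        "row,expected", [([0, 0, 5, 1], 0.5), ([0, 0, 0, 0], 0.0), ([1, 2, 3, 4], 1.0)]
    )
    def test_detection_fraction(self, row, expected):
        counts = pd.DataFrame([row], index=["G"], columns=list("abcd"), dtype=float)
        assert markers.pct_expressed(counts, np.ones(4, bool), "G") == expected

    def test_empty_mask_rejected(self):
        counts = pd.DataFrame([[1.0]], index=["G"], columns=["a"])
        with pytest.raises(ValueError):
            markers.pct_expressed(counts, np.zeros(1, bool), "G")


class TestAUCScan:
    def _scan_single_gene(self, target_vals, rest_vals):
        values = np.concatenate([target_vals, rest_vals])
        expr = pd.DataFrame([values], index=["G"], dtype=float)
        mask = np.array([True] * len(target_vals) + [False] * len(rest_vals))
        return markers.auc_marker_scan(expr, mask, forced=())

    def test_perfect_separation(self):
        table = self._scan_single_gene([2, 3, 4], [0, 0, 1])
        assert table.loc[0, "auc"] == pytest.approx(1.0)

    def test_all_tied_is_half(self):
        table = self._scan_single_gene([1, 1, 1], [1, 1, 1])
        assert table.loc[0, "auc"] == pytest.approx(0.5)

    def test_interleaved_example_matches_pair_counting(self):
        table = self._scan_single_gene([0, 2], [1, 3])
        oracle = auc_pair_counting(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert table.loc[0, "auc"] == pytest.approx(oracle) == 0.25

    def test_matches_pair_counting_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 50))
            values = rng.poisson(2, size=(5, n)).astype(float)
            mask = np.zeros(n, bool)
            mask[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = True
            if mask.sum() < 2 or (~mask).sum() < 2:
                continue
            expr = pd.DataFrame(values, index=[f"G{i}" for i in range(5)])
            table = markers.auc_marker_scan(expr, mask, forced=()).set_index("gene")
            for g in expr.index:
                oracle = auc_pair_counting(
                    expr.loc[g].to_numpy()[mask], expr.loc[g].to_numpy()[~mask]
                )
                assert table.loc[g, "auc"] == pytest.approx(oracle, abs=1e-12)

    def test_scale_invariance(self, rng):
        expr = pd.DataFrame(rng.gamma(2, 1, size=(4, 30)), index=list("ABCD"))
        mask = np.arange(30) < 10
        a = markers.auc_marker_scan(expr, mask, forced=())
        b = markers.auc_marker_scan(expr * 7.3, mask, forced=())
        pd.testing.assert_frame_equal(a, b)

    def test_forced_markers_always_selected(self, rng):
        expr = pd.DataFrame(
            rng.poisson(3, size=(2, 40)).astype(float), index=["CXCR6", "BG1"]
        )
        table = markers.auc_marker_scan(expr, np.arange(40) < 15).set_index("gene")
        assert table.loc["CXCR6", "selected"]

    def test_degenerate_masks_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError):
            markers.auc_marker_scan(expr, np.array([True] + [False] * 9))


class TestDEGScreen:
    def test_min_pct_gate(self, rng):
        n = 40
        values = np.zeros((2, n))
        values[0, ::10] = 1.0            # ~10% detection everywhere
        values[1] = rng.gamma(2, 1, n)   # well detected
        expr = pd.DataFrame(values, index=["rare", "common"])
        out = markers.deg_screen(expr, np.arange(n) < 20, np.arange(n) >= 20)
        assert "rare" not in out["gene"].tolist()
        assert "common" in out["gene"].tolist()

    def test_identical_groups_not_significant(self, rng):
        half = rng.gamma(2, 1, size=(10, 25))
        expr = pd.DataFrame(np.hstack([half, half]), index=[f"G{i}" for i in range(10)])
        out = markers.deg_screen(expr, np.arange(50) < 25, np.arange(50) >= 25)
        assert (out["p_adj"] > 0.99).all()

    def test_planted_shift_detected_first(self, rng):
        n = 400
        values = rng.gamma(2, 1, size=(20, n))
        values[7, :200] *= 4.0
        expr = pd.DataFrame(values, index=[f"G{i}" for i in range(20)])
        out = markers.deg_screen(expr, np.arange(n) < 200, np.arange(n) >= 200)
        assert out.loc[0, "gene"] == "G7"
        assert out.loc[0, "lfc"] > 0

    def test_small_groups_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError):
            markers.deg_screen(expr, np.arange(5) < 2, np.arange(5) >= 2)


class TestProportionsAndDMedian:
    def _labeled(self):
        counts, ann = _tiny_cohort()
        return markers.label_cxcr6_cd8(counts, ann)

    def test_fractions(self):
        ann = self._labeled()
        table, _ = markers.proportion_table(ann)
        s1 = table.set_index("sample_id").loc["S1"]
        assert s1["frac_total"] == pytest.approx(1 / 4)
        assert s1["frac_cd8"] == pytest.approx(1 / 2)

    def test_missing_cd8_flagged(self):
        ann = self._labeled()
        ann.loc[ann.sample_id == "S2", "t_subset"] = "CD4T"
        ann.loc[ann.sample_id == "S2", "cxcr6_status"] = "na"
        table, _ = markers.proportion_table(ann)
        assert np.isnan(table.set_index("sample_id").loc["S2", "frac_cd8"])

    def test_identical_paired_fractions_give_p_one(self):
        ann = self._labeled()
        # make S2 mirror S1 exactly (same subject, other tissue)
        ann.loc["c5", "cxcr6_status"] = "pos"
        ann.loc["c4", "cxcr6_status"] = "neg"
        _, tests = markers.proportion_table(ann)
        assert tests["frac_cd8"]["paired_p"] == pytest.approx(1.0)

    def _scores(self, ann):
        values = np.arange(len(ann), dtype=float) / 10
        return pd.DataFrame([values], index=["t_cytotoxicity"], columns=ann.index)

    def test_d_median_example(self):
        ann = self._labeled()
        scores = pd.DataFrame(
            [[0.2, 0.4, 0.6, 0.0, 0.1, 0.2, 0.3, 0.0]],
            index=["s"], columns=ann.index,
        )
        group = ann["t_subset"].isin(["CD8T", "CD4T"]).to_numpy()
        rec = markers.d_median(scores, ann, "s", cell_group=group)
        assert rec.d_median == pytest.approx(0.4 - 0.2)

    def test_antisymmetry_under_tissue_swap(self):
        ann = self._labeled()
        scores = self._scores(ann)
        rec = markers.d_median(scores, ann, "t_cytotoxicity")
        swapped = ann.copy()
        swapped["tissue"] = swapped["tissue"].map({"Tumor": "Normal", "Normal": "Tumor"})
        rec2 = markers.d_median(scores, swapped, "t_cytotoxicity")
        assert rec.d_median == pytest.approx(-rec2.d_median)

    def test_paired_only_matches_manual_filter(self):
        ann = self._labeled()
        extra = pd.DataFrame(
            {
                "sample_id": ["S3"] * 2, "subject_id": ["P9"] * 2,
                "tissue": ["Tumor"] * 2, "broad_type": ["TNKILC"] * 2,
                "t_subset": ["CD8T"] * 2, "cxcr6_status": ["pos", "neg"],
            },
            index=["x0", "x1"],
        )
        full = pd.concat([ann, extra])
        values = np.linspace(0, 1, len(full))
        scores = pd.DataFrame([values], index=["s"], columns=full.index)
        rec = markers.d_median(scores, full, "s", paired_only=True)
        manual = markers.d_median(scores[ann.index], ann, "s")
        assert rec.d_median == pytest.approx(manual.d_median)
        assert rec.n_tumor == manual.n_tumor

    def test_empty_group_rejected(self):
        ann = self._labeled()
        ann["tissue"] = "Tumor"
        with pytest.raises(ValueError):
            markers.d_median(self._scores(ann), ann, "t_cytotoxicity")
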