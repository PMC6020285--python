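"""Orientation, intersection, concordance classification and rank sums."""

import numpy as np
import pandas as pd
import pytest

from crossde import classify, intersect_common, orient, rank_concordant
from crossde.concord import (
    CONCORDANT_NEGATIVE,
    CONCORDANT_POSITIVE,
    DISCORDANT,
    ConcordantGene,
    as_detections,
    concordance_table,
)
from crossde.diffexpr import DETable, UP, DOWN
from crossde.errors import ValidationError


def de_table(fc_map, fdr_map=None, numerator="Cyc", denominator="Veh"):
    genes = list(fc_map)
    fc = np.array([fc_map[g] for g in genes], dtype=float)
    fdr = np.array([(fdr_map or {}).get(g, 0.5) for g in genes], dtype=float)
    frame = pd.DataFrame(
        {
            "mean_a": fc, "mean_b": np.ones_like(fc),
            "fc": fc, "log2fc": np.log2(fc),
            "p": fdr, "fdr": fdr,
            "direction": np.where(fc > 1, UP, np.where(fc < 1, DOWN, "flat")),
        },
        index=genes,
    )
    return DETable(f"{numerator}_vs_{denominator}", numerator, denominator, frame)


class TestOrient:
    def test_reciprocal_flip(self):
        t = orient(de_table({"g": 0.5}), flip=True)
        row = t.frame.loc["g"]
        assert row["fc"] == pytest.approx(2.0)
        assert row["log2fc"] == pytest.approx(1.0)
        assert row["direction"] == UP
        assert (t.numerator, t.denominator) == ("Veh", "Cyc")

    def test_double_flip_is_identity(self):
        t0 = de_table({"a": 0.4, "b": 2.5}, {"a": 0.1, "b": 0.2})
        t2 = orient(orient(t0, flip=True), flip=True)
        pd.testing.assert_frame_equal(t0.frame, t2.frame)
        assert (t2.numerator, t2.denominator) == (t0.numerator, t0.denominator)

    def test_inhibitor_convention(self):
        # a positively regulated gene measured as inhibitor/vehicle (fc < 1)
        # appears upregulated once reported vehicle/inhibitor
        t = orient(de_table({"Gli1": 1 / 1.61}), flip=True)
        assert t.frame.loc["Gli1", "fc"] == pytest.approx(1.61)
        assert t.frame.loc["Gli1", "direction"] == UP

    def test_p_and_fdr_untouched(self):
        t0 = de_table({"a": 0.4}, {"a": 0.07})
        t1 = orient(t0, flip=True)
        assert t1.frame.loc["a", "p"] == t0.frame.loc["a", "p"]
        assert t1.frame.loc["a", "fdr"] == t0.frame.loc["a", "fdr"]


class TestIntersectCommon:
    def test_direction_ignored(self):
        a = {("a", UP), ("b", UP), ("c", DOWN)}
        b = {("b", DOWN), ("c", DOWN), ("d", UP)}
        assert intersect_common(a, b) == ["b", "c"]

    def test_disjoint(self):
        assert intersect_common({("a", UP)}, {("b", UP)}) == []

    def test_identical(self):
        s = {("x", UP), ("y", DOWN)}
        assert intersect_common(s, s) == ["x", "y"]


class TestClassify:
    def _tables(self):
        vitro = de_table(
            {"Gli1": 25.62, "Gas1": 0.2610966, "Edn1": 2.0, "Flat": 1.0},
            {"Gli1": 9e-6, "Gas1": 8.5e-5, "Edn1": 1e-3, "Flat": 0.5},
            numerator="SHH",
        )
        vivo = de_table(
            {"Gli1": 1.61, "Gas1": 0.8547009, "Edn1": 0.8, "Flat": 1.2},
            {"Gli1": 0.104969, "Gas1": 0.749637, "Edn1": 0.3, "Flat": 0.4},
        )
        return vitro, vivo

    def test_published_example_rows(self):
        vitro, vivo = self._tables()
        out = {g.gene: g for g in classify(["Gli1", "Gas1", "Edn1"], vitro, vivo)}
        assert out["Gli1"].klass == CONCORDANT_POSITIVE
        assert out["Gas1"].klass == CONCORDANT_NEGATIVE
        assert out["Edn1"].klass == DISCORDANT  # 2.0 up vitro, 0.8 down vivo

    def test_flat_fold_change_is_discordant(self):
        vitro, vivo = self._tables()
        (g,) = classify(["Flat"], vitro, vivo)
        assert g.klass == DISCORDANT

    def test_partition_identity(self):
        vitro, vivo = self._tables()
        genes = ["Gli1", "Gas1", "Edn1", "Flat"]
        out = classify(genes, vitro, vivo)
        n_pos = sum(g.klass == CONCORDANT_POSITIVE for g in out)
        n_neg = sum(g.klass == CONCORDANT_NEGATIVE for g in out)
        n_disc = sum(g.klass == DISCORDANT for g in out)
        assert n_pos + n_neg + n_disc == len(genes)
        meta = concordance_table(out).metadata
        assert meta["n_concordant_up"] + meta["n_concordant_down"] + meta["n_discordant"] == meta["n_common"]

    def test_input_order_invariance(self):
        vitro, vivo = self._tables()
        a = classify(["Gli1", "Gas1", "Edn1"], vitro, vivo)
        b = classify(["Edn1", "Gli1", "Gas1"], vitro, vivo)
        assert {g.gene: g.klass for g in a} == {g.gene: g.klass for g in b}

    def test_missing_gene_errors(self):
        vitro, vivo = self._tables()
        with pytest.raises(ValidationError, match="Nope"):
            classify(["Nope"], vitro, vivo)

    def test_as_detections_vocabulary(self):
        vitro, vivo = self._tables()
        det = as_detections(classify(["Gli1", "Gas1", "Edn1"], vitro, vivo))
        assert det == {("Gli1", "positive"), ("Gas1", "negative")}


def cg(gene, fc_vitro, fc_vivo, fdr_vitro=0.001, klass=CONCORDANT_POSITIVE):
    return ConcordantGene(
        gene=gene, fc_vitro=fc_vitro, fdr_vitro=fdr_vitro,
        fc_vivo=fc_vivo, fdr_vivo=0.5, klass=klass,
    )


class TestRankConcordant:
    def test_hand_enumeration_with_fdr_tiebreak(self):
        genes = [
            cg("A", 10.0, 1.5, fdr_vitro=1e-5),
            cg("B", 5.0, 1.8, fdr_vitro=1e-3),
            cg("C", 2.0, 1.2, fdr_vitro=1e-2),
        ]
        table = rank_concordant(genes).frame
        # A: vitro rank 1 + vivo rank 2 = 3; B: 2 + 1 = 3; C: 3 + 3 = 6
        assert list(table["gene"]) == ["A", "B", "C"]  # A before B by smaller fdr
        assert list(table["rank_sum"]) == [3.0, 3.0, 6.0]

    def test_single_gene_rank_sum_two(self):
        table = rank_concordant([cg("X", 3.0, 1.4)]).frame
        assert table.loc[0, "rank_sum"] == 2.0

    def test_identical_fc_average_ranks(self):
        genes = [cg("A", 4.0, 1.5), cg("B", 4.0, 1.5)]
        table = rank_concordant(genes).frame
        assert list(table["rank_sum"]) == [3.0, 3.0]
        assert set(table["rank_vitro"]) == {1.5}

    def test_negative_class_smallest_fc_first(self):
        genes = [
            cg("Edn1", 0.262, 0.680, klass=CONCORDANT_NEGATIVE),
            cg("Lamb1", 0.694, 0.877, klass=CONCORDANT_NEGATIVE),
        ]
        table = rank_concordant(genes).frame
        assert list(table["gene"]) == ["Edn1", "Lamb1"]  # strongest repression first

    def test_mixed_classes_rejected(self):
        genes = [cg("A", 2.0, 1.5), cg("B", 0.5, 0.8, klass=CONCORDANT_NEGATIVE)]
        with pytest.raises(ValidationError, match="mixed"):
            rank_concordant(genes)
        with pytest.raises(ValidationError, match="discordant"):
            rank_concordant([cg("D", 2.0, 0.8, klass=DISCORDANT)])

    def test_monotone_transform_invariance(self, rng):
        fcs_v = 1 + rng.random(15) * 10
        fcs_w = 1 + rng.random(15)
        genes = [cg(f"g{i}", fcs_v[i], fcs_w[i]) for i in range(15)]
        base = list(rank_concordant(genes).frame["gene"])
        cubed = [cg(f"g{i}", fcs_v[i] ** 3, fcs_w[i] ** 3) for i in range(15)]
        assert list(rank_concordant(cubed).frame["gene"]) == base

    def test_top_k_truncation_and_zero_means_all(self):
        genes = [cg(f"g{i}", 2.0 + i, 1.1 + 0.01 * i) for i in range(8)]
        assert len(rank_concordant(genes, top_k=3)) == 3
        assert len(rank_concordant(genes, top_k=0)) == 8

    def test_empty_input_gives_empty_table(self):
        assert len(rank_concordant([])) == 0
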