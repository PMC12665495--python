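import numpy as np
import pandas as pd
import pytest

from lrxtalk import (
    GroupExpression,
    LRPairTable,
    export_circos_edges,
    interaction_scores,
    normalize_total,
    pair_log_fold_change,
    participation_proportions,
    percent_change,
    top_k_pairs,
    total_interaction_matrix,
)
from lrxtalk._errors import DataError
from lrxtalk.interactome import InteractionSummary, InteractionTensor
from lrxtalk.lr_resource import LRPair


def normalized_expr(values, genes, groups, tp="0w"):
    return normalize_total(GroupExpression(np.asarray(values, float), genes, groups, tp))


def make_tensor(scores, labels, pairs, tp="0w"):
    return InteractionTensor(np.asarray(scores, float), labels, pairs, tp)


ONE_PAIR = LRPairTable([LRPair("L1", "R1")])
TWO_PAIRS = LRPairTable([LRPair("L1", "R1"), LRPair("L2", "R2")])


class TestInteractionScores:
    def test_outer_product_entries(self):
        # L across (A,B) = (2,0), R = (3,1); scores before normalization 6,2,0,0
        lig = GroupExpression(np.array([[2.0, 0.0]]), ["L1"], ["A", "B"], "0w")
        rec = GroupExpression(np.array([[3.0, 1.0]]), ["R1"], ["A", "B"], "0w")
        lign, recn = normalize_total(lig), normalize_total(rec)
        tensor = interaction_scores(lign, recn, ONE_PAIR)
        expected = np.outer(lign.values[0], recn.values[0])
        np.testing.assert_allclose(tensor.scores[0], expected, rtol=1e-12)
        # structure mirrors the raw outer product [[6,2],[0,0]] up to scaling
        ratio = tensor.scores[0, 0, 0] / tensor.scores[0, 0, 1]
        assert ratio == pytest.approx(3.0)
        assert tensor.scores[0, 1, :].sum() == 0.0

    def test_absent_gene_scores_zero_and_flagged(self):
        lig = normalized_expr([[1.0, 1.0]], ["L1"], ["A", "B"])
        rec = normalized_expr([[1.0, 1.0]], ["R1"], ["A", "B"])
        pairs = LRPairTable([LRPair("L1", "R1"), LRPair("Lx", "R1")])
        tensor = interaction_scores(lig, rec, pairs)
        assert tensor.missing_pairs == ["Lx-R1"]
        np.testing.assert_allclose(tensor.scores[1], 0.0)

    def test_unnormalized_input_rejected(self):
        lig = GroupExpression(np.array([[1.0]]), ["L1"], ["A"], "0w")
        rec = normalized_expr([[1.0]], ["R1"], ["A"])
        with pytest.raises(DataError, match="normalized"):
            interaction_scores(lig, rec, ONE_PAIR)

    def test_mismatched_groups_rejected(self):
        lig = normalized_expr([[1.0, 1.0]], ["L1"], ["A", "B"])
        rec = normalized_expr([[1.0, 1.0]], ["R1"], ["A", "C"])
        with pytest.raises(DataError, match="group labels"):
            interaction_scores(lig, rec, ONE_PAIR)

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(21)
        n_genes, n_types, n_pairs = 8, 3, 5
        genes = [f"g{i}" for i in range(n_genes)]
        types = ["A", "B", "C"]
        combos = {
            (genes[rng.integers(n_genes)], genes[rng.integers(n_genes)])
            for _ in range(20)
        }
        pairs = LRPairTable([LRPair(l, r) for l, r in sorted(combos)][:n_pairs])
        expr = normalized_expr(rng.integers(0, 9, size=(n_genes, n_types)), genes, types)
        tensor = interaction_scores(expr, expr, pairs)
        for k, p in enumerate(pairs):
            L = expr.gene_vector(p.ligand)
            R = expr.gene_vector(p.receptor)
            for i in range(n_types):
                for j in range(n_types):
                    assert tensor.scores[k, i, j] == L[i] * R[j]

    def test_rank_one_cross_ratio_property(self):
        rng = np.random.default_rng(22)
        expr = normalized_expr(rng.random((6, 4)) + 0.5, [f"g{i}" for i in range(6)],
                               list("ABCD"))
        pairs = LRPairTable([LRPair("g0", "g1"), LRPair("g2", "g3")])
        tensor = interaction_scores(expr, expr, pairs)
        for A in tensor.scores:
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        for l in range(4):
                            assert A[i, j] * A[k, l] == pytest.approx(
                                A[i, l] * A[k, j], rel=1e-9
                            )


class TestTotalAndProportions:
    def test_single_pair_total_is_its_matrix(self):
        scores = [[[1.0, 2.0], [3.0, 4.0]]]
        t = make_tensor(scores, ["A", "B"], ONE_PAIR)
        summary = total_interaction_matrix(t)
        np.testing.assert_allclose(summary.total_matrix, scores[0])

    def test_additivity_over_pairs(self):
        block = [[1.0, 2.0], [3.0, 4.0]]
        t = make_tensor([block, block], ["A", "B"], TWO_PAIRS)
        summary = total_interaction_matrix(t)
        np.testing.assert_allclose(summary.total_matrix, 2 * np.asarray(block))

    def test_grand_total_closed_form(self):
        """Per pair the grand total is (sum_i L_i) * (sum_j R_j)."""
        rng = np.random.default_rng(23)
        genes = ["L1", "L2", "R1", "R2"]
        expr = normalized_expr(rng.random((4, 3)) + 0.1, genes, list("ABC"))
        pairs = LRPairTable([LRPair("L1", "R1"), LRPair("L2", "R2")])
        tensor = interaction_scores(expr, expr, pairs)
        closed = sum(
            expr.gene_vector(p.ligand).sum() * expr.gene_vector(p.receptor).sum()
            for p in pairs
        )
        assert total_interaction_matrix(tensor).grand_total == pytest.approx(closed)

    def test_both_sides_proportions_by_endpoint_counting(self):
        # enumerate endpoints: every unit of weight contributes one ligand
        # and one receptor endpoint; [[1,1],[1,1]] is symmetric -> (1/2, 1/2)
        summary = InteractionSummary(np.ones((2, 2)), np.array(["A", "B"]), "0w")
        props = participation_proportions(summary, "both-sides")
        np.testing.assert_allclose(props.to_numpy(), [0.5, 0.5])

    def test_ligand_mode_forced(self):
        summary = InteractionSummary(
            np.array([[3.0, 1.0], [0.0, 0.0]]), np.array(["A", "B"]), "0w"
        )
        props = participation_proportions(summary, "ligand")
        np.testing.assert_allclose(props.to_numpy(), [1.0, 0.0])

    def test_single_type_proportion_is_one(self):
        summary = InteractionSummary(np.array([[2.0]]), np.array(["A"]), "0w")
        assert participation_proportions(summary).iloc[0] == 1.0

    @pytest.mark.parametrize("mode", ["both-sides", "ligand", "receptor"])
    def test_proportions_sum_to_one(self, mode):
        rng = np.random.default_rng(24)
        summary = InteractionSummary(rng.random((5, 5)), np.array(list("ABCDE")), "0w")
        assert participation_proportions(summary, mode).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_errors(self):
        summary = InteractionSummary(np.zeros((2, 2)), np.array(["A", "B"]), "0w")
        with pytest.raises(DataError):
            participation_proportions(summary)


class TestPercentChange:
    def s(self, value):
        return InteractionSummary(np.array([[value]]), np.array(["A"]), "x")

    def test_identical_is_zero(self):
        assert percent_change(self.s(5.0), self.s(5.0), "A", "A") == 0.0

    def test_doubling_is_plus_100(self):
        assert percent_change(self.s(10.0), self.s(5.0), "A", "A") == pytest.approx(100.0)

    def test_12_to_9_is_minus_25(self):
        assert percent_change(self.s(9.0), self.s(12.0), "A", "A") == pytest.approx(-25.0)

    def test_zero_reference_errors(self):
        with pytest.raises(DataError, match="zero"):
            percent_change(self.s(1.0), self.s(0.0), "A", "A")


class TestTopKPairs:
    def make(self, entries):
        pairs = LRPairTable([LRPair(l, r) for l, r, _ in entries])
        scores = np.array([[[s]] for _, _, s in entries])
        return make_tensor(scores, ["A"], pairs)

    def test_sorted_descending(self):
        t = self.make([("a", "x", 5.0), ("b", "y", 2.0), ("c", "z", 9.0)])
        out = top_k_pairs(t, "A", "A", 3)
        assert list(out["score"]) == [9.0, 5.0, 2.0]

    def test_ties_break_lexicographically(self):
        t = self.make([("b", "y", 5.0), ("a", "z", 5.0), ("a", "x", 5.0)])
        out = top_k_pairs(t, "A", "A", 3)
        assert list(zip(out["ligand"], out["receptor"])) == [
            ("a", "x"), ("a", "z"), ("b", "y")
        ]

    def test_k_exceeding_pairs_returns_all(self):
        t = self.make([("a", "x", 1.0)])
        assert len(top_k_pairs(t, "A", "A", 10)) == 1

    def test_unknown_label_errors(self):
        t = self.make([("a", "x", 1.0)])
        with pytest.raises(DataError, match="unknown cell type"):
            top_k_pairs(t, "Z", "A", 1)


class TestLogFoldChange:
    def pair_tensors(self, ref, alt):
        pairs = LRPairTable([LRPair(f"L{i}", f"R{i}") for i in range(len(ref))])
        t_ref = make_tensor(np.array(ref)[:, None, None], ["A"], pairs, "0w")
        t_alt = make_tensor(np.array(alt)[:, None, None], ["A"], pairs, "12w")
        return t_alt, t_ref

    def test_doubling_gives_plus_one(self):
        t_alt, t_ref = self.pair_tensors([2.0], [4.0])
        lfc = pair_log_fold_change(t_alt, t_ref, "A", "A", pseudocount=0.0)
        assert lfc.iloc[0] == pytest.approx(1.0)

    def test_unchanged_gives_zero(self):
        t_alt, t_ref = self.pair_tensors([3.0], [3.0])
        assert pair_log_fold_change(t_alt, t_ref, "A", "A", 0.0).iloc[0] == 0.0

    def test_pseudocount_applies_to_zero(self):
        t_alt, t_ref = self.pair_tensors([0.0], [1.0])
        lfc = pair_log_fold_change(t_alt, t_ref, "A", "A", pseudocount=1.0)
        assert lfc.iloc[0] == pytest.approx(1.0)  # log2(2/1)

    def test_zero_both_sides_omitted(self):
        t_alt, t_ref = self.pair_tensors([0.0, 1.0], [0.0, 2.0])
        lfc = pair_log_fold_change(t_alt, t_ref, "A", "A", pseudocount=1.0)
        assert list(lfc.index) == ["L1-R1"]

    def test_zero_pseudocount_with_one_sided_zero_errors(self):
        t_alt, t_ref = self.pair_tensors([1.0], [0.0])
        with pytest.raises(DataError, match="pseudocount"):
            pair_log_fold_change(t_alt, t_ref, "A", "A", pseudocount=0.0)


class TestCircosExport:
    def test_all_edges_with_zero_flag(self, tmp_path):
        summary = InteractionSummary(
            np.array([[1.0, 0.0], [2.0, 3.0]]), np.array(["A", "B"]), "0w"
        )
        df = export_circos_edges(summary, tmp_path / "e.tsv", include_zero=True)
        assert len(df) == 4

    def test_weight_conservation(self, tmp_path):
        rng = np.random.default_rng(31)
        summary = InteractionSummary(rng.random((3, 3)), np.array(list("ABC")), "0w")
        path = tmp_path / "e.tsv"
        export_circos_edges(summary, path)
        back = pd.read_csv(path, sep="\t")
        assert back["weight"].sum() == pytest.approx(summary.grand_total, rel=1e-9)

    def test_byte_identical_across_runs(self, tmp_path):
        summary = InteractionSummary(
            np.array([[0.1234567891, 7.0], [3.0, 0.0]]), np.array(["B", "A"]), "0w"
        )
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        export_circos_edges(summary, p1)
        export_circos_edges(summary, p2)
        assert p1.read_bytes() == p2.read_bytes()
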