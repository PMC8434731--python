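"""Gene feature construction, the gene weight layer and self-attention."""

import numpy as np
import pytest

from swnet.chem import DrugSimilarityMatrix, FingerprintBitSet, InputError
from swnet.genomics import (
    AttentionMap,
    GeneFeatureSet,
    GeneWeightLayer,
    apply_self_attention,
    attention_map,
    collapse_mutations,
    combine_gene_features,
    extract_top_weight_genes,
    infer_new_drug_weight,
    merge_gene_lists,
    top_k_weight_genes,
    zscore_per_cell,
)

E = np.e


class TestZScore:
    def test_three_point_row(self):
        z = zscore_per_cell(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(z, [[-1.224744871, 0.0, 1.224744871]])

    def test_constant_row_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_per_cell(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert np.array_equal(z[0], np.zeros(3))
        assert z[1].std() == pytest.approx(1.0)

    def test_rows_are_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore_per_cell(rng.normal(2.0, 3.0, (10, 25)))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            zscore_per_cell(np.empty((0, 0)))


class TestCollapseMutations:
    def test_idempotent_collapse_and_consequence_filter(self):
        records = [
            ("c1", "gA", "missense"),
            ("c1", "gA", "nonsense"),  # second hit, still 1
            ("c1", "gB", "silent"),  # synonymous: ignored
        ]
        m = collapse_mutations(records, ["c1", "c2"], ["gA", "gB"])
        assert m.tolist() == [[1.0, 0.0], [0.0, 0.0]]

    def test_empty_input_gives_zero_matrix(self):
        m = collapse_mutations([], ["c1"], ["gA"])
        assert m.tolist() == [[0.0]]

    def test_unknown_ids_rejected_with_offenders(self):
        with pytest.raises(InputError, match="cX"):
            collapse_mutations([("cX", "gA", "missense")], ["c1"], ["gA"])

    def test_matches_per_record_scan_oracle(self):
        rng = np.random.default_rng(1)
        cells = [f"c{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(5)]
        kinds = ["missense", "silent", "nonsense", "intronic"]
        records = [
            (cells[rng.integers(6)], genes[rng.integers(5)], kinds[rng.integers(4)])
            for _ in range(40)
        ]
        got = collapse_mutations(records, cells, genes)
        want = np.zeros((6, 5))
        for c, g, k in records:  # brute-force scan
            if k in ("missense", "nonsense"):
                want[cells.index(c), genes.index(g)] = 1
        assert np.array_equal(got, want)


class TestMergeGeneLists:
    def test_union_intersection_dedup(self):
        assert merge_gene_lists(["A", "B"], ["B", "C"], ["A", "B", "C"]) == ["A", "B", "C"]
        assert merge_gene_lists(["A", "B"], ["B", "C"], ["A", "B"]) == ["A", "B"]
        assert merge_gene_lists(["A", "A"], [], ["A"]) == ["A"]

    def test_empty_result_rejected(self):
        with pytest.raises(InputError):
            merge_gene_lists(["A"], ["B"], ["C"])


class TestCombine:
    def test_elementwise_formula(self):
        out = combine_gene_features([1.0, 2.0], [1.0, 0.0], [0.5, 0.5])
        assert out.tolist() == [1.5, 2.0]

    @pytest.mark.parametrize("mut,w", [([0, 0], [3.0, 4.0]), ([1, 1], [0.0, 0.0])])
    def test_null_mutation_or_weight_returns_expression(self, mut, w):
        expr = np.array([0.3, -1.2])
        assert np.array_equal(combine_gene_features(expr, mut, w), expr)

    def test_masked_addition_equivalence(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(size=20)
        mut = (rng.random(20) < 0.3).astype(float)
        w = rng.normal(size=20)
        out = combine_gene_features(expr, mut, w)
        assert np.array_equal(out[mut == 0], expr[mut == 0])
        assert np.allclose(out[mut == 1], expr[mut == 1] + w[mut == 1])

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            combine_gene_features([1.0], [1.0, 2.0], [1.0, 2.0])


def _sim(values, ids=None):
    values = np.asarray(values, dtype=float)
    return DrugSimilarityMatrix(drug_ids=ids or list(range(len(values))), values=values)


class TestAttention:
    def test_two_drug_identity_similarity(self):
        amap = attention_map(_sim([[1, 0], [0, 1]]))
        p = E / (E + 1)
        assert np.allclose(amap.values, [[p, 1 - p], [1 - p, p]], atol=1e-9)

    def test_uniform_rows_for_constant_similarity(self):
        amap = attention_map(_sim(np.ones((4, 4))))
        assert np.allclose(amap.values, 0.25)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, (5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        amap = attention_map(_sim(v))
        assert np.allclose(amap.values.sum(axis=1), 1.0, atol=1e-12)

    def test_shift_invariance_of_softmax(self):
        # softmax ignores a constant added to a whole row; build two valid
        # similarity matrices whose off-diagonal rows differ by a constant
        a = attention_map(_sim([[1.0, 0.2, 0.4], [0.2, 1.0, 0.1], [0.4, 0.1, 1.0]]))
        row = np.array([1.0, 0.2, 0.4])
        shifted = np.exp(row + 0.3) / np.exp(row + 0.3).sum()
        assert np.allclose(a.values[0], shifted, atol=1e-12)


class TestSelfAttention:
    def test_identical_rows_are_fixed_point(self):
        r = np.array([0.1, 0.9, 0.4])
        W = GeneWeightLayer(mode="multi", weights=np.tile(r, (3, 1)), drug_ids=list("abc"))
        amap = attention_map(_sim(np.ones((3, 3))))
        out = apply_self_attention(W, amap)
        assert np.allclose(out.weights, np.tile(r, (3, 1)))

    def test_two_by_two_matrix_product(self):
        p = E / (E + 1)
        amap = AttentionMap(values=np.array([[p, 1 - p], [1 - p, p]]))
        W = GeneWeightLayer(mode="multi", weights=np.eye(2), drug_ids=["a", "b"])
        out = apply_self_attention(W, amap)
        assert np.allclose(out.weights, [[p, 1 - p], [1 - p, p]], atol=1e-9)

    def test_applied_to_identity_reproduces_map(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 1, (4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        amap = attention_map(_sim(v))
        W = GeneWeightLayer(mode="multi", weights=np.eye(4), drug_ids=list("abcd"))
        out = apply_self_attention(W, amap)
        assert np.allclose(out.weights, amap.values, atol=1e-12)

    def test_rows_stay_in_convex_hull(self):
        rng = np.random.default_rng(5)
        W = GeneWeightLayer(mode="multi", weights=rng.normal(size=(4, 7)), drug_ids=list("abcd"))
        v = rng.uniform(0, 1, (4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        out = apply_self_attention(W, attention_map(_sim(v)))
        lo, hi = W.weights.min(axis=0), W.weights.max(axis=0)
        assert np.all(out.weights >= lo - 1e-12)
        assert np.all(out.weights <= hi + 1e-12)

    def test_linear_in_W(self):
        rng = np.random.default_rng(6)
        v = np.eye(3) * 0.5 + 0.5
        amap = attention_map(_sim(v))
        A = rng.normal(size=(3, 5))
        B = rng.normal(size=(3, 5))
        mk = lambda w: GeneWeightLayer(mode="multi", weights=w, drug_ids=list("abc"))
        lhs = apply_self_attention(mk(2 * A + 3 * B), amap).weights
        rhs = 2 * apply_self_attention(mk(A), amap).weights + 3 * apply_self_attention(mk(B), amap).weights
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestNewDrugWeight:
    def test_single_training_drug_returns_its_row(self):
        fp = FingerprintBitSet(on_bits={1, 2}, n_bits=8)
        W = GeneWeightLayer(mode="multi", weights=np.array([[0.3, 0.7]]), drug_ids=["a"])
        out = infer_new_drug_weight(fp, [fp], W)
        assert np.allclose(out, [0.3, 0.7])

    def test_weighted_toward_identical_training_drug(self):
        fp_a = FingerprintBitSet(on_bits={1, 2, 3}, n_bits=16)
        fp_b = FingerprintBitSet(on_bits={8, 9}, n_bits=16)
        W = GeneWeightLayer(mode="multi", weights=np.array([[1.0, 0.0], [0.0, 1.0]]),
                            drug_ids=["a", "b"])
        out = infer_new_drug_weight(fp_a, [fp_a, fp_b], W)
        # softmax([1, 0]) puts the larger coefficient on the identical drug
        assert out[0] > out[1]
        assert out[0] == pytest.approx(E / (E + 1), abs=1e-9)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(7)
        fps = [FingerprintBitSet(on_bits=set(rng.integers(0, 32, 5).tolist()), n_bits=32)
               for _ in range(4)]
        W = GeneWeightLayer(mode="multi", weights=rng.normal(size=(4, 6)),
                            drug_ids=list("abcd"))
        out = infer_new_drug_weight(fps[0], fps, W)
        assert np.all(out >= W.weights.min(axis=0) - 1e-12)
        assert np.all(out <= W.weights.max(axis=0) + 1e-12)

    def test_empty_training_set_rejected(self):
        fp = FingerprintBitSet(on_bits={1}, n_bits=8)
        W = GeneWeightLayer(mode="multi", weights=np.zeros((1, 2)), drug_ids=["a"])
        with pytest.raises(InputError):
            infer_new_drug_weight(fp, [], W)


class TestTopWeightGenes:
    def test_argmax_and_minmax_normalization(self):
        assert extract_top_weight_genes([0.1, 1.0, 0.5], ["g1", "g2", "g3"]) == ["g2"]
        assert extract_top_weight_genes([2.0, 4.0, 3.0], ["g1", "g2", "g3"]) == ["g2"]

    def test_ties_all_reported(self):
        assert extract_top_weight_genes([1.0, 1.0, 0.0], ["g1", "g2", "g3"]) == ["g1", "g2"]

    def test_constant_row_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            assert extract_top_weight_genes([2.0, 2.0], ["g1", "g2"]) == []

    def test_top_k_ordering(self):
        assert top_k_weight_genes([0.2, 0.9, 0.5, 0.1], list("abcd"), k=3) == ["b", "c", "a"]


class TestGeneFeatureSet:
    def test_shape_and_binary_validation(self):
        with pytest.raises(InputError, match="binary"):
            GeneFeatureSet(
                gene_ids=["g1", "g2"], cell_ids=["c1"],
                expression=zscore_per_cell(np.array([[1.0, 2.0]])),
                mutation=np.array([[0.5, 0.0]]),
            )

    def test_rejects_unnormalized_expression(self):
        with pytest.raises(InputError, match="z-scored"):
            GeneFeatureSet(
                gene_ids=["g1", "g2"], cell_ids=["c1"],
                expression=np.array([[5.0, 9.0]]),
                mutation=np.array([[0.0, 1.0]]),
            )

    def test_rows_for_unknown_cell(self):
        fs = GeneFeatureSet(
            gene_ids=["g1", "g2"], cell_ids=["c1"],
            expression=zscore_per_cell(np.array([[1.0, 2.0]])),
            mutation=np.array([[0.0, 1.0]]),
        )
        with pytest.raises(InputError, match="cX"):
            fs.rows_for("cX")
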