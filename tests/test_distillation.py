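import numpy as np
import pytest
import scipy.sparse as sp

from seqgauge import (
    ModelSpec,
    ValidationError,
    build_Tdecom,
    build_Tsort,
    build_Tthin,
    count_gauge,
    count_params,
    design_matrix,
    distill,
    distinct_subsets_with_multiplicity,
    enumerate_model_classes,
    enumerate_sequences,
    model_preset,
    model_rep,
    onehot_single,
    random_pscp,
    similarity_T,
    simplex_single,
)
from seqgauge.distillation import build_Tthin_inverse

from conftest import AB, ABC, ABCD


class TestSimilarityT:
    def test_alpha_three_matrix(self):
        T, _ = similarity_T(ABC)
        assert T.tolist() == [[1, 1, 1], [1, 0, -1], [0, 1, -1]]

    def test_alpha_two_matrix(self):
        T, _ = similarity_T(AB)
        assert T.tolist() == [[1, 1], [1, -1]]

    @pytest.mark.parametrize("alphabet", [AB, ABC, ABCD])
    def test_splits_onehot_into_trivial_plus_simplex(self, alphabet):
        T, T_inv = similarity_T(alphabet)
        assert np.allclose(T @ T_inv, np.eye(alphabet.alpha))
        for c in alphabet:
            expected = np.concatenate([[1], simplex_single(c, alphabet)])
            assert np.array_equal(T @ onehot_single(c, alphabet), expected)

    def test_last_character_example(self):
        T, _ = similarity_T(ABC)
        assert (T @ np.array([0, 0, 1])).tolist() == [1, -1, -1]


class TestTdecom:
    def test_constant_model_trivial(self):
        D, blocks = build_Tdecom(ModelSpec(ABC, 2, "one-hot", [()]))
        assert D.toarray().tolist() == [[1]]
        assert blocks.blocks[0].subset == ()

    def test_single_position_block_layout(self):
        spec = ModelSpec(ABC, 2, "one-hot", [(1,)])
        D, blocks = build_Tdecom(spec)
        assert [(b.subset, b.dim) for b in blocks.blocks] == [((), 1), ((1,), 2)]
        T, _ = similarity_T(ABC)
        assert np.array_equal(D.toarray(), T)

    def test_pairwise_multiplicities(self):
        L = 3
        spec = model_preset("pairwise", ABC, L)
        subsets, mult = distinct_subsets_with_multiplicity(spec)
        by_subset = dict(zip(subsets, mult))
        assert by_subset[()] == 1 + L + L * (L - 1) // 2
        assert all(by_subset[(l,)] == L for l in range(1, L + 1))
        assert all(by_subset[(l, m)] == 1 for l in range(1, L) for m in range(l + 1, L + 1))

    def test_blocks_per_source_set(self):
        spec = model_preset("all-order", AB, 2)
        _, blocks = build_Tdecom(spec)
        per_source = {}
        for b in blocks.blocks:
            per_source[b.source] = per_source.get(b.source, 0) + 1
        # each position set A_j expands into 2^|A_j| sub-blocks
        assert [per_source[j] for j in range(spec.J)] == [1, 2, 2, 4]


class TestTthinTsort:
    def test_no_redundancy_gives_identity_thinning(self):
        spec = model_preset("pairwise", ABC, 2, flavor="simplex")
        _, blocks = build_Tdecom(spec)
        assert (build_Tthin(blocks) != sp.identity(blocks.M)).nnz == 0

    def test_thinning_zeroes_redundant_copies(self):
        # after decomposition, every non-kept copy maps to exactly 0 on all
        # sequence embeddings (checked exhaustively at alpha=3, L=3)
        spec = model_preset("pairwise", ABC, 3)
        D, blocks = build_Tdecom(spec)
        thin = build_Tthin(blocks)
        kept = blocks.kept_copies()
        X = design_matrix(spec)
        Y = (thin @ D @ X.T).T
        for b in blocks.blocks:
            block_vals = Y[:, b.offset : b.offset + b.dim]
            if kept[b.subset].offset == b.offset:
                continue
            assert np.all(block_vals == 0)

    def test_thin_inverse(self):
        spec = model_preset("additive", ABC, 3)
        _, blocks = build_Tdecom(spec)
        thin, thin_inv = build_Tthin(blocks), build_Tthin_inverse(blocks)
        assert (thin @ thin_inv != sp.identity(blocks.M)).nnz == 0

    def test_sort_is_orthogonal_permutation(self):
        spec = model_preset("pairwise", ABC, 2)
        _, blocks = build_Tdecom(spec)
        S = build_Tsort(blocks)
        assert S.nnz == blocks.M
        assert (S.T @ S != sp.identity(blocks.M)).nnz == 0


class TestDistill:
    def test_constant_model(self):
        res = distill(ModelSpec(ABC, 2, "one-hot", [()]))
        assert res.gamma == 0 and res.Tdist.toarray().tolist() == [[1]]

    def test_pairwise_distills_to_pairwise_simplex(self):
        res = distill(model_preset("pairwise", ABC, 3))
        expected = model_preset("pairwise", ABC, 3, flavor="simplex")
        assert res.distilled_spec.position_sets == expected.position_sets

    def test_all_order_dimensions(self):
        res = distill(model_preset("all-order", ABC, 3))
        assert res.M == 64 and res.gamma == 37 and res.distilled_dim == 27

    def test_inverse_assembled_from_factors(self, suite_spec):
        res = distill(suite_spec)
        I = (res.Tdist @ res.Tdist_inverse).toarray()
        assert np.allclose(I, np.eye(res.M), atol=1e-12)

    def test_duplicate_position_sets(self):
        spec = ModelSpec(AB, 2, "one-hot", [(), (1,), (1,)])
        res = distill(spec)
        assert res.gamma == count_gauge(spec) == 3  # two extra trivials + one extra simplex
        X = design_matrix(spec)
        Y = (res.Tdist @ X.T).T
        assert np.all(Y[:, res.distilled_dim :] == 0)

    def test_simplex_flavor_already_distilled(self):
        spec = model_preset("pairwise", ABC, 2, flavor="simplex")
        res = distill(spec)
        assert res.gamma == 0
        assert res.distilled_dim == spec.n_features

    def test_redundant_representation_block_structure(self, rng):
        # Tdist R(h) Tdist^-1 splits into a distilled and a redundant block
        spec = model_preset("pairwise", ABC, 2)
        res = distill(spec)
        d = res.distilled_dim
        for _ in range(5):
            h = random_pscp(ABC, 2, rng)
            C = np.asarray(res.Tdist @ model_rep(spec, h) @ res.Tdist_inverse)
            assert np.allclose(C[d:, :d], 0) and np.allclose(C[:d, d:], 0)


class TestCounting:
    def test_pairwise_closed_forms(self):
        for alphabet, L in [(AB, 3), (ABC, 4), (ABCD, 5)]:
            a = alphabet.alpha
            spec = model_preset("pairwise", alphabet, L)
            pairs = L * (L - 1) // 2
            assert count_params(spec) == 1 + L * a + pairs * a**2
            assert count_gauge(spec) == L + pairs * (2 * a - 1)

    def test_all_order_counts(self):
        spec = model_preset("all-order", ABC, 3)
        assert count_params(spec) == 64
        assert count_gauge(spec) == 64 - 27

    def test_k_order_param_count(self):
        from math import comb

        spec = model_preset("K-order", ABCD, 5, K=2)
        assert count_params(spec) == comb(5, 2) * 4**2

    def test_scales_to_large_L_without_matrices(self):
        L = 1000
        spec = model_preset("pairwise", ABCD, L)
        pairs = L * (L - 1) // 2
        assert count_params(spec) == 1 + 4 * L + 16 * pairs
        assert count_gauge(spec) == L + pairs * 7

    def test_single_term_models_have_no_gauge(self):
        assert count_gauge(ModelSpec(ABC, 3, "one-hot", [(1, 3)])) == 0

    def test_multi_term_lower_bound(self, rng):
        # any generalized one-hot model with J >= 2 orbits has >= J-1 freedoms
        for _ in range(20):
            J = int(rng.integers(2, 6))
            sets = []
            for _ in range(J):
                size = int(rng.integers(0, 4))
                sets.append(tuple(sorted(rng.choice(3, size=size, replace=False) + 1)))
            spec = ModelSpec(ABC, 3, "one-hot", sets)
            assert count_gauge(spec) >= J - 1


class TestSparsity:
    def test_pairwise_nnz_grows_quadratically(self):
        # nonzero count of Tdist for the pairwise model at fixed alpha should
        # scale like the number of parameters, O(L^2), not explode
        nnz = {}
        for L in (4, 8, 16):
            res = distill(model_preset("pairwise", ABCD, L))
            nnz[L] = res.Tdist.nnz
        assert nnz[8] / nnz[4] < 6
        assert nnz[16] / nnz[8] < 6


class TestClassEnumeration:
    @pytest.mark.parametrize("L, expected", [(1, 4), (2, 16), (3, 256)])
    def test_class_counts(self, L, expected):
        classes = enumerate_model_classes(L)
        assert len(classes) == expected
        families = {c.position_sets for c in classes}
        assert len(families) == expected  # all distinct subset families

    def test_classes_have_no_gauge_freedoms(self):
        assert all(count_gauge(c) == 0 for c in enumerate_model_classes(2))

    def test_length_cap(self):
        with pytest.raises(ValidationError):
            enumerate_model_classes(5)
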