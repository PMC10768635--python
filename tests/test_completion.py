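import numpy as np
import pytest

from tigers.completion import (
    CPFactors,
    TTCores,
    TensorCompletionModel,
    cp_gradient,
    cp_reconstruct,
    fit_completion,
    fold,
    impute,
    khatri_rao,
    matricize,
    tt_gradient,
    tt_reconstruct,
)
from tigers.errors import DataError


def finite_difference(objective, blocks, h=1e-6):
    """Central finite differences of a scalar function of a list of arrays."""
    grads = []
    for n, block in enumerate(blocks):
        g = np.zeros_like(block)
        for idx in np.ndindex(block.shape):
            orig = block[idx]
            block[idx] = orig + h
            fp = objective()
            block[idx] = orig - h
            fm = objective()
            block[idx] = orig
            g[idx] = (fp - fm) / (2 * h)
        grads.append(g)
    return grads


class TestKhatriRao:
    def test_single_matrix_identity(self, rng):
        a = rng.normal(size=(3, 2))
        assert np.array_equal(khatri_rao([a]), a)

    def test_columnwise_kronecker(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        # oracle: per-column Kronecker by direct enumeration
        expected = np.column_stack([np.kron(a[:, r], b[:, r]) for r in range(2)])
        out = khatri_rao([a, b])
        assert np.array_equal(out, expected)
        assert out.tolist() == [[0, 2], [1, 0], [0, 4], [3, 0]]

    def test_zero_absorbing(self, rng):
        a = rng.normal(size=(4, 3))
        assert not khatri_rao([a, np.zeros((2, 3))]).any()

    def test_mismatched_columns_error(self, rng):
        with pytest.raises(DataError):
            khatri_rao([rng.normal(size=(2, 2)), rng.normal(size=(2, 3))])


class TestReconstruct:
    def test_cp_all_ones_gives_rank(self):
        factors = CPFactors([np.ones((1, 4))] * 3)
        assert cp_reconstruct(factors).item() == pytest.approx(4.0)

    def test_cp_rank_one_outer_product(self):
        factors = CPFactors([np.array([[1.0], [2.0]]), np.array([[3.0], [4.0]]), np.array([[5.0]])])
        out = cp_reconstruct(factors)
        expected = np.einsum("i,j,k->ijk", [1.0, 2.0], [3.0, 4.0], [5.0])
        assert np.allclose(out, expected)
        assert sorted(out.ravel().tolist()) == [15.0, 20.0, 30.0, 40.0]

    def test_cp_entries_match_index_formula(self, planted_cp, rng):
        factors, tensor = planted_cp
        for _ in range(10):
            i, j, k = (rng.integers(s) for s in tensor.shape)
            expected = sum(
                factors.factors[0][i, r] * factors.factors[1][j, r] * factors.factors[2][k, r]
                for r in range(factors.rank)
            )
            assert tensor[i, j, k] == pytest.approx(expected, rel=1e-12)

    def test_tt_rank_one_all_ones(self):
        cores = TTCores([np.ones((1, 2, 1)), np.ones((1, 3, 1)), np.ones((1, 4, 1))])
        assert np.array_equal(tt_reconstruct(cores), np.ones((2, 3, 4)))

    def test_tt_two_mode_dot_product(self):
        cores = TTCores([np.array([[[1.0, 2.0]]]), np.array([[[3.0]], [[4.0]]])])
        assert tt_reconstruct(cores).item() == pytest.approx(11.0)

    def test_tt_entries_match_slice_products(self, planted_tt, rng):
        cores, tensor = planted_tt
        g = cores.cores
        for _ in range(10):
            i, j, k = (rng.integers(s) for s in tensor.shape)
            expected = (g[0][:, i, :] @ g[1][:, j, :] @ g[2][:, k, :]).item()
            assert tensor[i, j, k] == pytest.approx(expected, rel=1e-12)

    def test_zero_core_gives_zero_tensor(self, planted_tt):
        cores, _ = planted_tt
        zeroed = cores.copy()
        zeroed.cores[1][:] = 0.0
        assert not tt_reconstruct(zeroed).any()


class TestMatricize:
    def test_round_trip(self, rng):
        tensor = rng.normal(size=(3, 4, 5))
        for mode in range(3):
            assert np.array_equal(fold(matricize(tensor, mode), mode, tensor.shape), tensor)

    def test_cp_matricization_identity(self, planted_cp):
        # X_(n) = A^(n) (A^(N) kr ... kr A^(n+1) kr A^(n-1) kr ... kr A^(1))^T
        factors, tensor = planted_cp
        fs = factors.factors
        for n in range(3):
            others = [fs[m] for m in range(3) if m != n][::-1]
            assert np.allclose(matricize(tensor, n), fs[n] @ khatri_rao(others).T)

    def test_tt_matricization_identity(self, planted_tt):
        # X_(n) = G^(n)_(2) (G^{>n}_(1) kron G^{<n}_(n))
        from tigers.completion import _tt_interface

        cores, tensor = planted_tt
        for n in range(3):
            core = cores.cores[n]
            g2 = matricize(np.asarray(core), 1)
            g_right, g_left = _tt_interface(cores, n)
            assert np.allclose(matricize(tensor, n), g2 @ np.kron(g_right, g_left))

    def test_degenerate_and_errors(self):
        assert matricize(np.full((1, 1, 1), 3.0), 0).item() == 3.0
        with pytest.raises(DataError):
            matricize(np.zeros((2, 2)), 5)


class TestGradients:
    @pytest.mark.parametrize("method", ["cp", "tt"])
    def test_zero_residual_zero_gradient(self, method, planted_cp, planted_tt):
        params, tensor = planted_cp if method == "cp" else planted_tt
        mask = np.ones(tensor.shape)
        grad_fn = cp_gradient if method == "cp" else tt_gradient
        grads = grad_fn(params, mask * tensor, mask)
        assert all(np.allclose(g, 0.0, atol=1e-9) for g in grads)

    @pytest.mark.parametrize("method", ["cp", "tt"])
    def test_unit_scalar_case(self, method):
        # 1x1x1 tensor, all parameters 1, Y=0: residual 1, each gradient 1
        if method == "cp":
            params = CPFactors([np.ones((1, 1))] * 3)
            grads = cp_gradient(params, np.zeros((1, 1, 1)), np.ones((1, 1, 1)))
        else:
            params = TTCores([np.ones((1, 1, 1))] * 3)
            grads = tt_gradient(params, np.zeros((1, 1, 1)), np.ones((1, 1, 1)))
        for g in grads:
            assert g.item() == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["cp", "tt"])
    @pytest.mark.parametrize("observed", [1.0, 0.5])
    def test_matches_finite_differences(self, method, observed, rng):
        shape = (3, 4, 5)
        X = rng.normal(size=shape)
        mask = (rng.random(shape) < observed).astype(float)
        Y = mask * X
        if method == "cp":
            params = CPFactors([rng.normal(size=(i, 2)) for i in shape])
            analytic = cp_gradient(params, Y, mask)
            blocks = params.factors

            def objective():
                return 0.5 * np.sum((Y - mask * cp_reconstruct(params)) ** 2)

        else:
            params = TTCores(
                [rng.normal(size=(1, 3, 2)), rng.normal(size=(2, 4, 2)), rng.normal(size=(2, 5, 1))]
            )
            analytic = tt_gradient(params, Y, mask)
            blocks = params.cores

            def objective():
                return 0.5 * np.sum((Y - mask * tt_reconstruct(params)) ** 2)

        numeric = finite_difference(objective, blocks)
        for a, n in zip(analytic, numeric):
            assert np.max(np.abs(a - n)) / max(np.max(np.abs(n)), 1e-12) < 1e-5


class TestFit:
    def test_zero_budget_returns_initialization(self, planted_cp):
        _, tensor = planted_cp
        model = TensorCompletionModel(tensor, np.ones(tensor.shape), method="cp", rank=2)
        res = model.fit(max_iterations=0, seed=3)
        assert len(res.trace) == 1
        init = model._init_params(3)
        assert all(np.array_equal(a, b) for a, b in zip(res.params.factors, init.factors))

    def test_fully_observed_rank1_converges(self, rng):
        shape = (4, 20, 30)
        truth = cp_reconstruct(CPFactors([rng.normal(size=(i, 1)) for i in shape]))
        model = TensorCompletionModel(truth, np.ones(shape), method="cp", rank=1)
        res = model.fit(max_iterations=100, seed=0, tol=0.0)
        assert res.objective < 1e-8 * res.trace[0].objective

    def test_trace_objective_matches_definition(self, planted_tt, rng):
        _, tensor = planted_tt
        mask = (rng.random(tensor.shape) < 0.7).astype(float)
        model = TensorCompletionModel(tensor, mask, method="tt", rank=(1, 2, 2, 1))
        res = model.fit(max_iterations=20, seed=1)
        recon = res.reconstruct()
        direct = 0.5 * np.sum((mask * (tensor - recon)) ** 2)
        assert res.objective == pytest.approx(direct, rel=1e-10)

    def test_monotone_trace(self, planted_cp, rng):
        _, tensor = planted_cp
        mask = (rng.random(tensor.shape) < 0.8).astype(float)
        res = TensorCompletionModel(tensor, mask, method="cp", rank=2).fit(50, seed=2)
        objs = res.objective_trace()
        assert (np.diff(objs) <= 1e-12).all()

    def test_seed_determinism(self, planted_cp):
        _, tensor = planted_cp
        mask = np.ones(tensor.shape)
        run = lambda: TensorCompletionModel(tensor, mask, method="cp", rank=2).fit(30, seed=11)
        a, b = run(), run()
        assert all(np.array_equal(x, y) for x, y in zip(a.params.factors, b.params.factors))
        assert np.array_equal(a.objective_trace(), b.objective_trace())

    def test_all_missing_rejected(self):
        with pytest.raises(DataError):
            TensorCompletionModel(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))

    def test_invalid_rank_specs(self):
        data, mask = np.ones((2, 2, 2)), np.ones((2, 2, 2))
        with pytest.raises(DataError):
            TensorCompletionModel(data, mask, method="cp", rank=0)
        with pytest.raises(DataError):
            TensorCompletionModel(data, mask, method="tt", rank=(2, 2, 2, 1))
        with pytest.raises(DataError):
            TensorCompletionModel(data, mask, method="bogus")

    def test_summary_mentions_method_and_shape(self, planted_cp):
        _, tensor = planted_cp
        res = TensorCompletionModel(tensor, np.ones(tensor.shape), "cp", 2).fit(5, seed=0)
        text = res.summary()
        assert "CP" in text and str(tensor.shape) in text


class TestImpute:
    def test_all_observed_returns_input(self, planted_cp, rng):
        factors, tensor = planted_cp
        out = impute(tensor, np.ones(tensor.shape), factors)
        assert np.array_equal(out, tensor)

    def test_all_missing_returns_reconstruction(self, planted_cp):
        factors, tensor = planted_cp
        out = impute(tensor, np.zeros(tensor.shape), factors)
        assert np.array_equal(out, cp_reconstruct(factors))

    def test_mixed_mask_blend(self, planted_tt, rng):
        cores, tensor = planted_tt
        noisy = tensor + rng.normal(size=tensor.shape)
        mask = (rng.random(tensor.shape) < 0.5).astype(float)
        out = impute(noisy, mask, cores)
        recon = tt_reconstruct(cores)
        # oracle: entry-by-entry blend definition
        expected = np.where(mask == 1, noisy, recon)
        assert np.array_equal(out, expected)

    def test_observed_entries_bit_identical(self, planted_cp, rng):
        factors, tensor = planted_cp
        mask = (rng.random(tensor.shape) < 0.5).astype(float)
        out = impute(tensor, mask, factors)
        assert np.array_equal(out[mask == 1], tensor[mask == 1])


def test_fit_completion_function_surface(planted_cp):
    _, tensor = planted_cp
    params, trace = fit_completion(tensor, np.ones(tensor.shape), method="cp", rank_spec=2,
                                   max_iterations=10, seed=0)
    assert isinstance(params, CPFactors)
    assert trace[0].iteration == 0 and trace[-1].iteration <= 10
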