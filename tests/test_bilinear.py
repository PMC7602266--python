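"""Stacked algebra, alternating-SVD fitting, and closed-form user adaptation."""

import numpy as np
import pytest

from emgsign import bilinear as bl
from emgsign.synthetic import BilinearGenConfig, generate_bilinear_instance


def random_instance(rng, I=2, J=3, C=4, U=5, M=3, N=2):
    Z = rng.standard_normal((I, U))
    W = bl.StackedMatrix(rng.standard_normal((I * C, J)), C)
    X = rng.standard_normal((J, M * N))
    return Z, W, X, (I, J, C, U, M, N)


# ---------------------------------------------------------------------------
# Stacked transpose
# ---------------------------------------------------------------------------

def test_stacked_transpose_examples_and_involution(rng):
    a = bl.StackedMatrix.from_blocks([[[1, 2], [3, 4]], [[5, 6], [7, 8]]])
    st = bl.stacked_transpose(a)
    np.testing.assert_array_equal(
        st.data, [[1, 3], [2, 4], [5, 7], [6, 8]]
    )
    for _ in range(100):
        m, n, c = rng.integers(1, 6, size=3)
        x = bl.StackedMatrix(rng.standard_normal((c * m, n)), int(c))
        # involution
        np.testing.assert_array_equal(
            bl.stacked_transpose(bl.stacked_transpose(x)).data, x.data
        )
    single = bl.StackedMatrix(rng.standard_normal((4, 7)), 1)
    np.testing.assert_array_equal(bl.stacked_transpose(single).data, single.data.T)


def test_stacked_matrix_validation():
    with pytest.raises(ValueError):
        bl.StackedMatrix(np.zeros((5, 2)), 2)  # 5 rows not divisible by 2
    with pytest.raises(ValueError):
        bl.StackedMatrix(np.array([[np.nan, 1.0]]), 1)
    with pytest.raises(ValueError):
        bl.StackedMatrix.from_blocks([np.zeros((2, 2)), np.zeros((3, 2))])


def test_stack_layout_owns_the_index_map(rng):
    Z, W, X, dims = random_instance(rng)
    I, J, C, U, M, N = dims
    Y = bl.compose(Z, W, X)
    for c in range(C):
        for u in range(U):
            for m in range(M):
                for n in range(N):
                    row, col = bl.stack_layout(c, u, m, n, (C, U, M, N))
                    expected = Z[:, u] @ Y_block_w(W, c) @ X[:, m * N + n]
                    assert Y.data[row, col] == pytest.approx(expected, rel=1e-12, abs=1e-12)
    with pytest.raises(IndexError):
        bl.stack_layout(C, 0, 0, 0, (C, U, M, N))


def Y_block_w(W, c):
    return W.blocks()[c]


# ---------------------------------------------------------------------------
# Composition and objective
# ---------------------------------------------------------------------------

def test_compose_matches_entrywise_oracle_and_st_identity(rng):
    for _ in range(100):
        Z, W, X, dims = random_instance(rng)
        I, J, C, U, M, N = dims
        Y = bl.compose(Z, W, X)
        # brute-force quadruple loop
        oracle = np.empty((C * U, M * N))
        for c in range(C):
            for u in range(U):
                for m in range(M):
                    for n in range(N):
                        r, col = bl.stack_layout(c, u, m, n, (C, U, M, N))
                        oracle[r, col] = float(Z[:, u] @ W.blocks()[c] @ X[:, m * N + n])
        scale = np.linalg.norm(oracle)
        assert np.linalg.norm(Y.data - oracle) <= 1e-10 * scale
        # the two equivalent compositions agree: Y^ST = [W X]^ST Z
        lhs = bl.stacked_transpose(Y).data
        rhs = bl.stacked_transpose(bl.StackedMatrix(W.data @ X, C)).data @ Z
        assert np.linalg.norm(lhs - rhs) <= 1e-10 * scale


def test_compose_scalar_case():
    Y = bl.compose(
        np.array([[2.0]]), bl.StackedMatrix(np.array([[3.0]]), 1), np.array([[5.0]])
    )
    np.testing.assert_allclose(Y.data, [[30.0]])


def test_objective_examples_and_loop_oracle(rng):
    Z, W, X, dims = random_instance(rng)
    I, J, C, U, M, N = dims
    model = bl.BilinearModel(Z=Z, W=W, X=X, dims=dict(zip("IJCUMN", dims)))
    Y = bl.compose(Z, W, X)
    assert bl.objective(Y, model) == pytest.approx(0.0, abs=1e-18)
    zero_x = bl.BilinearModel(Z=Z, W=W, X=np.zeros_like(X), dims=model.dims)
    assert bl.objective(Y, zero_x) == pytest.approx(np.sum(Y.data**2))
    # perturbed instance vs quadruple loop
    Y2 = bl.StackedMatrix(Y.data + np.random.default_rng(1).standard_normal(Y.shape), C)
    e = 0.0
    for c in range(C):
        for u in range(U):
            for m in range(M):
                for n in range(N):
                    r, col = bl.stack_layout(c, u, m, n, (C, U, M, N))
                    e += (Y2.data[r, col] - Z[:, u] @ W.blocks()[c] @ X[:, m * N + n]) ** 2
    assert bl.objective(Y2, model) == pytest.approx(e, rel=1e-10)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_noise_free_instances():
    for seed in range(3):
        cfg = BilinearGenConfig(I=3, J=8, C=5, U=7, M=4, N=5, seed=seed)
        Y, *_ = generate_bilinear_instance(cfg)
        model = bl.fit(Y, cfg.dims)
        assert model.converged
        assert model.objective_history[-1] / np.sum(Y.data**2) <= 1e-8


def test_fit_full_rank_exact_reconstruction(rng):
    C, U, M, N = 3, 4, 3, 3
    Y = bl.StackedMatrix(rng.standard_normal((C * U, M * N)), C)
    model = bl.fit(Y, (U, M * N, C, U, M, N))
    assert model.objective_history[-1] / np.sum(Y.data**2) <= 1e-16


def test_fit_objective_history_non_increasing():
    cfg = BilinearGenConfig(I=3, J=10, C=6, U=10, M=5, N=8, noise_sd=0.5, seed=2)
    Y, *_ = generate_bilinear_instance(cfg)
    model = bl.fit(Y, (2, 6, 6, 10, 5, 8))  # under-dimensioned: iterates visibly
    h = model.objective_history
    assert len(h) >= 1
    for a, b in zip(h, h[1:]):
        assert b <= a + 1e-9 * h[0]


def test_fit_noisy_residual_tracks_noise_floor():
    """With entrywise noise sd sigma and dims matching the generator, the
    fitted per-entry residual approaches sigma^2 (model DOF are a small
    fraction of the data)."""
    sigma = 0.1
    ratios = []
    for seed in range(10):
        cfg = BilinearGenConfig(
            I=3, J=10, C=6, U=15, M=8, N=10, noise_sd=sigma, seed=seed
        )
        Y, *_ = generate_bilinear_instance(cfg)
        model = bl.fit(Y, cfg.dims)
        per_entry = model.objective_history[-1] / Y.data.size
        ratios.append(per_entry / sigma**2)
    assert abs(np.mean(ratios) - 1.0) <= 0.2


def test_fit_validates_inputs(rng):
    Y = bl.StackedMatrix(rng.standard_normal((6, 4)), 2)
    with pytest.raises(ValueError):
        bl.fit(Y, (4, 2, 2, 3, 2, 2))  # I > U
    with pytest.raises(ValueError):
        bl.fit(Y, (1, 5, 2, 3, 2, 2))  # J > M*N
    with pytest.raises(ValueError):
        bl.fit(bl.StackedMatrix(np.zeros((6, 4)), 2), (1, 2, 2, 3, 2, 2))


def test_fit_deterministic():
    cfg = BilinearGenConfig(I=2, J=5, C=4, U=6, M=3, N=4, noise_sd=0.2, seed=3)
    Y, *_ = generate_bilinear_instance(cfg)
    m1 = bl.fit(Y, cfg.dims)
    m2 = bl.fit(Y, cfg.dims)
    np.testing.assert_array_equal(m1.Z, m2.Z)
    np.testing.assert_array_equal(m1.X, m2.X)
    np.testing.assert_array_equal(m1.W.data, m2.W.data)


# ---------------------------------------------------------------------------
# New-user adaptation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_model():
    cfg = BilinearGenConfig(I=3, J=5, C=8, U=6, M=4, N=6, seed=11)
    Y, *_ = generate_bilinear_instance(cfg)
    return bl.fit(Y, cfg.dims)


def _new_user_data(model, z, cols=None):
    proj = bl._st(model.W.data, model.W.block_count) @ z[:, None]
    A = bl._st(proj, model.W.block_count)  # C x J
    X = model.X if cols is None else model.X[:, cols]
    return bl.StackedMatrix(A @ X, model.W.block_count)


def test_adaptation_recovers_generated_user(fitted_model, rng):
    model = fitted_model
    z_star = rng.standard_normal(model.I)
    N = model.dims["N"]
    y_cal = _new_user_data(model, z_star, cols=slice(0, N))  # motion 0, all reps
    result = bl.adapt_new_user(model, y_cal, 0)
    assert result.residual_relative <= 1e-8
    assert np.linalg.norm(result.z_new - z_star) <= 1e-8 * np.linalg.norm(z_star)


def test_adaptation_self_consistency_with_training_user(fitted_model):
    """A 'new' user identical to a training user recovers that motion's factors."""
    model = fitted_model
    u, m = 2, 1
    N = model.dims["N"]
    z_u = model.Z[:, u]
    y_cal = _new_user_data(model, z_u, cols=slice(m * N, (m + 1) * N))
    result = bl.adapt_new_user(model, y_cal, m)
    X_m = model.motion_columns(m)
    assert np.linalg.norm(result.X_new_m - X_m) <= 1e-6 * np.linalg.norm(X_m)


def test_adaptation_single_repetition_shapes(fitted_model, rng):
    model = fitted_model
    y = _new_user_data(model, rng.standard_normal(model.I), cols=slice(0, 1))
    result = bl.adapt_new_user(model, y, 0)
    assert result.z_new.shape == (model.I,)
    assert result.X_new_m.shape == (model.J, 1)
    assert result.W_new.data.shape == model.W.data.shape


def test_projection_consistency_and_linearity(fitted_model, rng):
    model = fitted_model
    z_star = rng.standard_normal(model.I)
    N = model.dims["N"]
    y_cal = _new_user_data(model, z_star, cols=slice(0, N))
    result = bl.adapt_new_user(model, y_cal, 0)
    # Projecting the calibration data with the adapted W reproduces X_new_m.
    np.testing.assert_allclose(
        bl.project_motions(result, y_cal, use_adapted_w=True),
        result.X_new_m,
        atol=1e-8,
    )
    y_all = _new_user_data(model, z_star)
    x = bl.project_motions(result, y_all)
    # Zero signal -> zero factors; scaling is linear.
    zero = bl.StackedMatrix(np.zeros((model.dims["C"], 3)), model.dims["C"])
    assert np.all(bl.project_motions(result, zero) == 0)
    scaled = bl.StackedMatrix(2.5 * y_all.data, y_all.block_count)
    np.testing.assert_allclose(bl.project_motions(result, scaled), 2.5 * x, rtol=1e-9)
    # Training-W projection recovers the model's own motion factors exactly.
    assert np.linalg.norm(x - model.X) <= 1e-8 * np.linalg.norm(model.X)


def test_adaptation_rejects_mismatched_channels(fitted_model, rng):
    bad = bl.StackedMatrix(rng.standard_normal((3, 4)), 3)
    with pytest.raises(ValueError):
        bl.adapt_new_user(fitted_model, bad, 0)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def test_grid_search_single_cell_and_ties():
    surface, best = bl.grid_search_ij([3], [7], lambda i, j: 0.5)
    assert surface == [(3, 7, 0.5)] and best == (3, 7)
    surface, best = bl.grid_search_ij([1, 2], [1, 2], lambda i, j: 1.0)
    assert best == (1, 1)  # ties toward the smaller pair
    with pytest.raises(ValueError):
        bl.grid_search_ij([], [1], lambda i, j: 0.0)

    def boom(i, j):
        raise RuntimeError("nope")

    with pytest.raises(RuntimeError, match=r"\(I=1, J=1\)"):
        bl.grid_search_ij([1], [1], boom)


def test_grid_search_prefers_generating_dims_region():
    """Accuracy surface is maximal once (I, J) reach the generating dims."""
    cfg = BilinearGenConfig(I=2, J=4, C=4, U=6, M=3, N=4, noise_sd=0.05, seed=5)
    Y, *_ = generate_bilinear_instance(cfg)

    def fit_quality(i, j):
        model = bl.fit(Y, (i, j, cfg.C, cfg.U, cfg.M, cfg.N))
        return 1.0 - model.objective_history[-1] / np.sum(Y.data**2)

    surface, best = bl.grid_search_ij([1, 2, 3], [2, 4, 6], fit_quality)
    scores = {(i, j): s for i, j, s in surface}
    assert scores[(2, 4)] >= scores[(1, 2)]
    assert best[0] >= 2 and best[1] >= 4
    # rerun is deterministic
    surface2, _ = bl.grid_search_ij([1, 2, 3], [2, 4, 6], fit_quality)
    assert surface == surface2
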