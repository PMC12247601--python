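"""Alignment estimators: identity baseline, scaled Procrustes, ridge map."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from brainalign import (
    CommonPair,
    IdentityAlign,
    ProcrustesModel,
    ResponseMatrix,
    RidgeAlignModel,
    ValidationError,
    apply_alignment,
    fit_anatomical,
    fit_procrustes,
    fit_ridge_alignment,
    load_model,
    save_model,
    subsample_alignment_set,
)
from brainalign.alignment import DEFAULT_ALPHA_GRID

from conftest import make_pair


def pair_from(S, T):
    ids = np.array([f"s{i:04d}" for i in range(S.shape[0])])
    return CommonPair(
        ResponseMatrix("src", ids, S), ResponseMatrix("tgt", ids, T)
    )


def random_orthogonal(dim, rng):
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


class TestAnatomical:
    def test_identity_model(self, rng):
        pair = make_pair(rng, n=10, v=4)
        model = fit_anatomical(pair)
        assert isinstance(model, IdentityAlign)
        out = apply_alignment(model, pair.source)
        assert np.array_equal(out.betas, pair.source.betas)

    def test_unequal_voxel_counts_rejected(self, rng):
        S = rng.standard_normal((8, 10))
        T = rng.standard_normal((8, 12))
        ids = np.array([f"s{i}" for i in range(8)])
        pair = CommonPair(
            ResponseMatrix("a", ids, S), ResponseMatrix("b", ids, T)
        )
        with pytest.raises(ValidationError, match="shared voxel grid"):
            fit_anatomical(pair)


class TestProcrustes:
    def test_self_alignment_gives_identity(self, rng):
        S = rng.standard_normal((20, 5))
        model = fit_procrustes(pair_from(S, S.copy()))
        assert np.allclose(model.R, np.eye(5), atol=1e-10)
        assert model.c == pytest.approx(1.0, abs=1e-10)

    def test_pure_scaling(self, rng):
        S = rng.standard_normal((20, 5))
        model = fit_procrustes(pair_from(S, 2.0 * S))
        assert np.allclose(model.R, np.eye(5), atol=1e-10)
        assert model.c == pytest.approx(2.0, abs=1e-10)

    def test_recovers_planted_rotation_and_scale(self, rng):
        S = rng.standard_normal((20, 5))
        R0 = random_orthogonal(5, rng)
        c0 = 1.7
        T = c0 * S @ R0
        model = fit_procrustes(pair_from(S, T))
        resid = np.linalg.norm(model.c * S @ model.R - T) / np.linalg.norm(T)
        assert resid < 1e-8
        assert np.abs(model.c * model.R - c0 * R0).max() < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_rotation_is_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        pair = make_pair(rng, n=15, v=6)
        model = fit_procrustes(pair)
        v = model.R.shape[0]
        assert np.abs(model.R.T @ model.R - np.eye(v)).max() < 1e-8

    def test_objective_beats_random_orthogonal_candidates(self, rng):
        """The SVD solution must not lose to any of 1,000 random (R, c*)
        candidates, c* being each candidate's optimal scale."""
        S = rng.standard_normal((10, 4))
        T = rng.standard_normal((10, 4))
        model = fit_procrustes(pair_from(S, T))
        fitted_obj = np.linalg.norm(model.c * S @ model.R - T) ** 2
        denom = np.trace(S.T @ S)
        for _ in range(1000):
            R = random_orthogonal(4, rng)
            c = np.trace(T.T @ (S @ R)) / denom
            assert fitted_obj <= np.linalg.norm(c * S @ R - T) ** 2 + 1e-9

    def test_rank_zero_source_rejected(self):
        ids = np.array(["a", "b"])
        pair = CommonPair(
            ResponseMatrix("s", ids, np.zeros((2, 3))),
            ResponseMatrix("t", ids, np.ones((2, 3))),
        )
        with pytest.raises(ValidationError, match="rank 0"):
            fit_procrustes(pair)


class TestRidgeAlignment:
    def test_self_map_is_identity(self, rng):
        S = rng.standard_normal((30, 6))
        model = fit_ridge_alignment(pair_from(S, S.copy()), alpha_grid=[0.0])
        assert np.abs(model.W - np.eye(6)).max() < 1e-6

    def test_recovers_planted_linear_map(self, rng):
        v = 6
        S = rng.standard_normal((3 * v, v))
        W0 = rng.standard_normal((v, v))
        model = fit_ridge_alignment(pair_from(S, S @ W0.T), alpha_grid=[0.0])
        assert np.abs(model.W - W0).max() < 1e-6

    @pytest.mark.parametrize("alpha", DEFAULT_ALPHA_GRID)
    def test_matches_normal_equations_and_sklearn(self, rng, alpha):
        S = rng.standard_normal((50, 10))
        T = rng.standard_normal((50, 8))
        model = fit_ridge_alignment(pair_from(S, T), alpha_grid=[alpha])
        # independent normal-equation oracle
        Wt = np.linalg.pinv(S.T @ S + alpha * np.eye(10)) @ S.T @ T
        assert np.abs(model.W - Wt.T).max() < 1e-8
        if alpha > 0:
            sk = Ridge(alpha=alpha, fit_intercept=False).fit(S, T)
            assert np.abs(model.W - sk.coef_).max() < 1e-6

    def test_cv_selects_from_grid_and_records_scores(self, rng):
        pair = make_pair(rng, n=40, v=5)
        model = fit_ridge_alignment(pair, n_folds=5, seed=0)
        assert model.alpha in DEFAULT_ALPHA_GRID
        assert len(model.cv_scores) == len(DEFAULT_ALPHA_GRID)

    def test_cv_is_deterministic_given_seed(self, rng):
        pair = make_pair(rng, n=40, v=5)
        a = fit_ridge_alignment(pair, seed=3)
        b = fit_ridge_alignment(pair, seed=3)
        assert a.alpha == b.alpha
        assert np.array_equal(a.cv_scores, b.cv_scores)
        assert np.array_equal(a.W, b.W)

    def test_shrinkage_monotone_in_alpha(self, rng):
        pair = make_pair(rng, n=30, v=6)
        norms = [
            np.linalg.norm(fit_ridge_alignment(pair, alpha_grid=[a]).W)
            for a in DEFAULT_ALPHA_GRID
        ]
        assert all(n1 >= n2 - 1e-12 for n1, n2 in zip(norms, norms[1:]))

    def test_rectangular_map_allowed(self, rng):
        S = rng.standard_normal((25, 4))
        T = rng.standard_normal((25, 7))
        model = fit_ridge_alignment(pair_from(S, T), alpha_grid=[1.0])
        assert model.W.shape == (7, 4)

    def test_invalid_inputs_rejected(self, rng):
        pair = make_pair(rng, n=10, v=3)
        with pytest.raises(ValidationError, match="empty"):
            fit_ridge_alignment(pair, alpha_grid=[])
        with pytest.raises(ValidationError, match="nonnegative"):
            fit_ridge_alignment(pair, alpha_grid=[-1.0])
        small = make_pair(rng, n=4, v=3)
        with pytest.raises(ValidationError, match="folds"):
            fit_ridge_alignment(small, n_folds=5)


class TestApplyAlignment:
    def test_procrustes_scalar_case_doubles(self, rng):
        X = make_pair(rng, n=7, v=4).source
        model = ProcrustesModel(R=np.eye(4), c=2.0)
        out = apply_alignment(model, X)
        assert np.allclose(out.betas, 2.0 * X.betas)
        assert np.array_equal(out.stimulus_ids, X.stimulus_ids)

    def test_ridge_matches_loop_product(self, rng):
        X = make_pair(rng, n=7, v=4).source
        W = rng.standard_normal((5, 4))
        out = apply_alignment(RidgeAlignModel(W=W, alpha=1.0), X)
        expected = np.zeros((7, 5))
        for i in range(7):
            for j in range(5):
                for l in range(4):
                    expected[i, j] += X.betas[i, l] * W[j, l]
        assert np.allclose(out.betas, expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X = make_pair(rng, n=5, v=4).source
        with pytest.raises(ValidationError, match="voxels"):
            apply_alignment(ProcrustesModel(R=np.eye(6), c=1.0), X)


class TestSubsample:
    def test_full_fraction_preserves_order(self, rng):
        pair = make_pair(rng, n=952, v=2)
        out = subsample_alignment_set(pair, 1.0, seed=0)
        assert np.array_equal(out.stimulus_ids, pair.stimulus_ids)

    @pytest.mark.parametrize(
        "fraction,expected", [(0.10, 95), (0.25, 238), (0.50, 476)]
    )
    def test_floor_sizing(self, rng, fraction, expected):
        pair = make_pair(rng, n=952, v=2)
        assert subsample_alignment_set(pair, fraction, seed=1).n_stimuli == expected

    def test_seed_determinism(self, rng):
        pair = make_pair(rng, n=100, v=2)
        a = subsample_alignment_set(pair, 0.3, seed=5)
        b = subsample_alignment_set(pair, 0.3, seed=5)
        c = subsample_alignment_set(pair, 0.3, seed=6)
        assert np.array_equal(a.stimulus_ids, b.stimulus_ids)
        assert not np.array_equal(a.stimulus_ids, c.stimulus_ids)

    def test_rows_stay_matched(self, rng):
        pair = make_pair(rng, n=50, v=3)
        sub = subsample_alignment_set(pair, 0.5, seed=2)
        for sid in sub.stimulus_ids:
            i_full = list(pair.stimulus_ids).index(sid)
            i_sub = list(sub.stimulus_ids).index(sid)
            assert np.array_equal(sub.source.betas[i_sub], pair.source.betas[i_full])
            assert np.array_equal(sub.target.betas[i_sub], pair.target.betas[i_full])

    def test_too_small_subset_rejected(self, rng):
        pair = make_pair(rng, n=10, v=2)
        with pytest.raises(ValidationError):
            subsample_alignment_set(pair, 0.1, seed=0)


class TestSerialization:
    def test_all_model_kinds_roundtrip(self, rng, tmp_path):
        pair = make_pair(rng, n=30, v=5)
        models = [
            fit_anatomical(pair),
            fit_procrustes(pair),
            fit_ridge_alignment(pair, seed=0),
        ]
        for i, model in enumerate(models):
            path = tmp_path / f"m{i}.npz"
            save_model(path, model)
            back = load_model(path)
            assert type(back) is type(model)
            out_a = apply_alignment(model, pair.source)
            out_b = apply_alignment(back, pair.source)
            assert np.array_equal(out_a.betas, out_b.betas)
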