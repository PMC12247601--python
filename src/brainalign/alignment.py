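"""Cross-subject alignment estimators.

Three ways to map a source subject's voxel space into a target subject's,
all fitted on responses to shared stimuli:

* **anatomical** — the identity map.  Both subjects' matrices already live
  in a shared template grid (e.g. MNI after registration), so anatomical
  alignment adds nothing beyond that registration.
* **hyperalignment** — scaled orthogonal Procrustes.  Finds the rotation
  ``R`` and scale ``c`` minimizing ``|c S R - T|_F^2`` via the SVD of
  ``P = S^T T``: ``R = U V^T`` and ``c = tr(T^T S R) / tr(S^T S)``.
* **ridge** — an unconstrained linear map.  Each target voxel is regressed
  on all source voxels, minimizing ``|S W^T - T|_F^2`` with an L2 penalty;
  the penalty weight is chosen by k-fold cross-validation over a grid.

Fitted models apply to *any* rows from the source subject, shared or not:
alignment is learned on the common stimuli and then transfers the whole
dataset into the target's functional space.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.metrics import r2_score

from .data import CommonPair, ResponseMatrix, ValidationError

#: Penalty grid searched by cross-validation, and the default chosen when
#: no search is requested.
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.0, 1.0, 10.0, 1e2, 1e3, 1e4)
DEFAULT_ALPHA: float = 1e3


@dataclasses.dataclass
class IdentityAlign:
    """Anatomical baseline: the identity map on a shared voxel grid."""

    v: int

    @property
    def source_dim(self) -> int:
        return self.v

    @property
    def target_dim(self) -> int:
        return self.v


@dataclasses.dataclass
class ProcrustesModel:
    """Scaled orthogonal map ``X -> c X R`` (hyperalignment)."""

    R: np.ndarray
    c: float
    mu_source: np.ndarray | None = None
    mu_target: np.ndarray | None = None

    @property
    def source_dim(self) -> int:
        return self.R.shape[0]

    @property
    def target_dim(self) -> int:
        return self.R.shape[1]


@dataclasses.dataclass
class RidgeAlignModel:
    """Linear voxel map ``X -> X W^T``.

    ``W`` has one row per *target* voxel holding the weights that estimate
    that voxel from all source voxels (the transpose of a column-per-voxel
    convention).  ``cv_scores`` records the mean cross-validated score for
    every candidate penalty, aligned with ``alpha_grid``.
    """

    W: np.ndarray
    alpha: float
    alpha_grid: tuple[float, ...] = (DEFAULT_ALPHA,)
    cv_scores: np.ndarray | None = None
    mu_source: np.ndarray | None = None
    mu_target: np.ndarray | None = None

    @property
    def source_dim(self) -> int:
        return self.W.shape[1]

    @property
    def target_dim(self) -> int:
        return self.W.shape[0]


AlignmentModel = Union[IdentityAlign, ProcrustesModel, RidgeAlignModel]


def fit_anatomical(pair: CommonPair) -> IdentityAlign:
    """Fit the anatomical (identity) baseline."""
    vs, vt = pair.source.n_voxels, pair.target.n_voxels
    if vs != vt:
        raise ValidationError(
            "anatomical baseline requires a shared voxel grid "
            f"(source has {vs} voxels, target {vt})"
        )
    return IdentityAlign(v=vs)


def fit_procrustes(pair: CommonPair, center: bool = False) -> ProcrustesModel:
    """Fit scaled orthogonal Procrustes on the common stimuli.

    Parameters
    ----------
    pair:
        Row-matched common responses (source ``S``, target ``T``), equal
        voxel counts.
    center:
        Subtract per-voxel means (fitted on the common set) before the
        fit; the means are stored and re-applied consistently. Off by
        default — the objective has no translation term.

    Notes
    -----
    ``R = U V^T`` from the SVD of ``P = S^T T`` is the orthogonal minimizer
    of ``|S R - T|_F``; the scale ``c = tr(T^T S R) / tr(S^T S)`` then
    minimizes over the scalar.  For degenerate inputs with repeated
    singular values one valid minimizer is returned.
    """
    S = pair.source.betas
    T = pair.target.betas
    if S.shape[1] != T.shape[1]:
        raise ValidationError(
            "Procrustes alignment requires equal source/target voxel counts"
        )
    mu_s = mu_t = None
    if center:
        mu_s = S.mean(axis=0)
        mu_t = T.mean(axis=0)
        S = S - mu_s
        T = T - mu_t
    denom = np.trace(S.T @ S)
    if denom <= 0.0:
        raise ValidationError("source common matrix has zero norm (rank 0)")
    P = S.T @ T
    U, _, Vt = np.linalg.svd(P)
    R = U @ Vt
    c = float(np.trace(T.T @ (S @ R)) / denom)
    return ProcrustesModel(R=R, c=c, mu_source=mu_s, mu_target=mu_t)


def _ridge_solve(S: np.ndarray, T: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form multi-output ridge: returns ``W^T = (S'S + aI)^-1 S'T``.

    ``alpha = 0`` falls back to the pseudo-inverse so rank-deficient
    designs return the minimum-norm solution instead of failing.
    """
    if alpha == 0.0:
        return np.linalg.lstsq(S, T, rcond=None)[0]
    v = S.shape[1]
    return np.linalg.solve(S.T @ S + alpha * np.eye(v), S.T @ T)


def fit_ridge_alignment(
    pair: CommonPair,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    center: bool = False,
) -> RidgeAlignModel:
    """Fit the ridge voxel map, selecting the penalty by cross-validation.

    Folds are formed by a seeded shuffle followed by contiguous splitting.
    The fold score is the coefficient of determination averaged across
    target voxels; the grid value with the best mean score wins, ties
    broken toward the larger (more regularized) penalty.  The returned
    ``W`` is the closed-form solution on the *full* common set at the
    selected penalty.
    """
    alpha_grid = tuple(float(a) for a in alpha_grid)
    if len(alpha_grid) == 0:
        raise ValidationError("alpha grid is empty")
    if any(a < 0 for a in alpha_grid):
        raise ValidationError("alpha values must be nonnegative")
    n = pair.n_stimuli
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    if n < n_folds:
        raise ValidationError(f"{n} common stimuli cannot fill {n_folds} folds")

    S = pair.source.betas
    T = pair.target.betas
    mu_s = mu_t = None
    if center:
        mu_s = S.mean(axis=0)
        mu_t = T.mean(axis=0)
        S = S - mu_s
        T = T - mu_t

    if len(alpha_grid) == 1:
        best_alpha = alpha_grid[0]
        cv_scores = None
    else:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        scores = np.zeros(len(alpha_grid))
        n_used = 0
        for val_idx in folds:
            if len(val_idx) < 2:  # R^2 undefined on a single validation row
                continue
            train_idx = np.setdiff1d(order, val_idx, assume_unique=True)
            S_tr, T_tr = S[train_idx], T[train_idx]
            S_va, T_va = S[val_idx], T[val_idx]
            for j, alpha in enumerate(alpha_grid):
                Wt = _ridge_solve(S_tr, T_tr, alpha)
                scores[j] += r2_score(
                    T_va, S_va @ Wt, multioutput="uniform_average"
                )
            n_used += 1
        cv_scores = scores / max(n_used, 1)
        # ties go to the larger alpha (more regularization)
        best_j = max(
            range(len(alpha_grid)), key=lambda j: (cv_scores[j], alpha_grid[j])
        )
        best_alpha = alpha_grid[best_j]

    W = _ridge_solve(S, T, best_alpha).T
    return RidgeAlignModel(
        W=W,
        alpha=best_alpha,
        alpha_grid=alpha_grid,
        cv_scores=cv_scores,
        mu_source=mu_s,
        mu_target=mu_t,
    )


def apply_alignment(model: AlignmentModel, X: ResponseMatrix) -> ResponseMatrix:
    """Map a source subject's rows into the target voxel space.

    Stimulus ids pass through unchanged; only the voxel axis is
    transformed.
    """
    if X.n_voxels != model.source_dim:
        raise ValidationError(
            f"model expects {model.source_dim} source voxels, got {X.n_voxels}"
        )
    B = X.betas
    if isinstance(model, IdentityAlign):
        out = B
    elif isinstance(model, ProcrustesModel):
        if model.mu_source is not None:
            out = model.c * ((B - model.mu_source) @ model.R) + model.mu_target
        else:
            out = model.c * (B @ model.R)
    elif isinstance(model, RidgeAlignModel):
        if model.mu_source is not None:
            out = (B - model.mu_source) @ model.W.T + model.mu_target
        else:
            out = B @ model.W.T
    else:  # pragma: no cover - guarded by the Union type
        raise TypeError(f"unknown alignment model {type(model).__name__}")
    return ResponseMatrix(X.subject_id, X.stimulus_ids, out)


def subsample_alignment_set(
    pair: CommonPair, fraction: float, seed: int = 0
) -> CommonPair:
    """Draw ``floor(fraction * n)`` matched rows without replacement.

    The same seeded uniform draw selects rows of source and target, so the
    pair stays row-matched.  ``fraction = 1.0`` returns the pair unchanged
    (original row order).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    n = pair.n_stimuli
    if fraction == 1.0:
        return pair
    m = int(np.floor(fraction * n))
    if m < 2:
        raise ValidationError(
            f"fraction {fraction} of {n} rows leaves {m} < 2 alignment rows"
        )
    rng = np.random.default_rng(seed)
    rows = rng.permutation(n)[:m]
    ids = pair.stimulus_ids[rows]
    return CommonPair(pair.source.subset(ids), pair.target.subset(ids))


# ---------------------------------------------------------------------------
# serialization

_KINDS = {"identity": IdentityAlign, "procrustes": ProcrustesModel, "ridge": RidgeAlignModel}


def save_model(path: str | Path, model: AlignmentModel) -> None:
    """Serialize an alignment model to the named-array container."""
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, IdentityAlign):
        arrays["kind"] = np.asarray("identity")
        arrays["v"] = np.asarray(model.v)
    elif isinstance(model, ProcrustesModel):
        arrays["kind"] = np.asarray("procrustes")
        arrays["R"] = model.R
        arrays["c"] = np.asarray(model.c)
        if model.mu_source is not None:
            arrays["mu_source"] = model.mu_source
            arrays["mu_target"] = model.mu_target
    elif isinstance(model, RidgeAlignModel):
        arrays["kind"] = np.asarray("ridge")
        arrays["W"] = model.W
        arrays["alpha"] = np.asarray(model.alpha)
        arrays["alpha_grid"] = np.asarray(model.alpha_grid)
        if model.cv_scores is not None:
            arrays["cv_scores"] = np.asarray(model.cv_scores)
        if model.mu_source is not None:
            arrays["mu_source"] = model.mu_source
            arrays["mu_target"] = model.mu_target
    else:
        raise TypeError(f"unknown alignment model {type(model).__name__}")
    np.savez(path, **arrays)


def load_model(path: str | Path) -> AlignmentModel:
    """Load an alignment model written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as npz:
        kind = str(npz["kind"])
        if kind == "identity":
            return IdentityAlign(v=int(npz["v"]))
        mu_s = npz["mu_source"] if "mu_source" in npz else None
        mu_t = npz["mu_target"] if "mu_target" in npz else None
        if kind == "procrustes":
            return ProcrustesModel(
                R=npz["R"], c=float(npz["c"]), mu_source=mu_s, mu_target=mu_t
            )
        if kind == "ridge":
            return RidgeAlignModel(
                W=npz["W"],
                alpha=float(npz["alpha"]),
                alpha_grid=tuple(npz["alpha_grid"].tolist()),
                cv_scores=npz["cv_scores"] if "cv_scores" in npz else None,
                mu_source=mu_s,
                mu_target=mu_t,
            )
    raise ValidationError(f"unknown model kind {kind!r}")
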