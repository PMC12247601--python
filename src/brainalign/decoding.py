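"""Linear decoding from voxel space to stimulus embeddings.

The decoder is a multi-output ridge regression from a subject's voxels to
a stimulus-embedding space — the linear stage of an embedding-based
reconstruction pipeline.  A fixed linear :class:`ImageRenderer` turns
embeddings into small images so pixel-level reconstruction metrics stay
computable without any generative model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .data import ResponseMatrix, ValidationError, order_ids
from .alignment import _ridge_solve


@dataclasses.dataclass
class StimulusEmbeddings:
    """Embedding vectors (``n`` stimuli by ``k`` dims) with row ids."""

    stimulus_ids: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        self.E = np.asarray(self.E, dtype=np.float64)
        if self.E.ndim != 2 or self.E.shape[0] != self.stimulus_ids.shape[0]:
            raise ValidationError("embedding rows must match stimulus_ids")
        if len(np.unique(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValidationError("stimulus_ids contains duplicates")
        if not np.all(np.isfinite(self.E)):
            raise ValidationError("embeddings contain non-finite values")

    @property
    def k(self) -> int:
        return self.E.shape[1]

    def subset(self, ids) -> "StimulusEmbeddings":
        ids = np.asarray(list(ids))
        pos = {sid: i for i, sid in enumerate(self.stimulus_ids.tolist())}
        try:
            rows = [pos[sid] for sid in ids.tolist()]
        except KeyError as exc:
            raise ValidationError(f"unknown stimulus id {exc.args[0]!r}") from exc
        return StimulusEmbeddings(ids, self.E[rows])


@dataclasses.dataclass
class LinearDecoder:
    """Ridge map from voxels to embeddings: ``E_hat = X B + intercept``."""

    B: np.ndarray
    intercept: np.ndarray
    alpha: float

    @property
    def n_voxels(self) -> int:
        return self.B.shape[0]

    @property
    def k(self) -> int:
        return self.B.shape[1]


@dataclasses.dataclass
class ImageRenderer:
    """Fixed linear map from embeddings to ``h x w`` images.

    ``G`` is a seeded random ``k x (h*w)`` matrix frozen at construction;
    rendering is exactly linear, so image-space structure mirrors
    embedding-space structure.
    """

    G: np.ndarray
    height: int
    width: int
    seed: int

    @classmethod
    def create(cls, k: int, height: int, width: int, seed: int) -> "ImageRenderer":
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((k, height * width))
        return cls(G=G, height=height, width=width, seed=seed)


def fit_linear_decoder(
    X: ResponseMatrix,
    E: StimulusEmbeddings,
    alpha: float = 10.0,
    fit_intercept: bool = False,
) -> LinearDecoder:
    """Fit the voxel-to-embedding ridge regression.

    Rows of ``X`` and ``E`` are matched by stimulus id (both reordered to
    the deterministic id order); an id mismatch is an error.  With
    ``fit_intercept`` both sides are mean-centered and the intercept
    absorbs the means; otherwise the intercept is zero.
    """
    if set(X.stimulus_ids.tolist()) != set(E.stimulus_ids.tolist()):
        raise ValidationError("stimulus ids of responses and embeddings differ")
    if alpha < 0:
        raise ValidationError("alpha must be nonnegative")
    X_ord = X.subset(X.stimulus_ids[order_ids(X.stimulus_ids)])
    E_ord = E.subset(X_ord.stimulus_ids)
    if X_ord.n_stimuli < 2:
        raise ValidationError("need at least 2 stimuli to fit a decoder")
    Xm, Em = X_ord.betas, E_ord.E
    if fit_intercept:
        mu_x = Xm.mean(axis=0)
        mu_e = Em.mean(axis=0)
        B = _ridge_solve(Xm - mu_x, Em - mu_e, alpha)
        intercept = mu_e - mu_x @ B
    else:
        B = _ridge_solve(Xm, Em, alpha)
        intercept = np.zeros(Em.shape[1])
    return LinearDecoder(B=B, intercept=intercept, alpha=float(alpha))


def predict_embeddings(dec: LinearDecoder, X: ResponseMatrix) -> StimulusEmbeddings:
    """Decode embeddings from voxel responses; ids pass through."""
    if X.n_voxels != dec.n_voxels:
        raise ValidationError(
            f"decoder expects {dec.n_voxels} voxels, got {X.n_voxels}"
        )
    return StimulusEmbeddings(X.stimulus_ids, X.betas @ dec.B + dec.intercept)


def render_images(E: StimulusEmbeddings, renderer: ImageRenderer) -> np.ndarray:
    """Render each embedding row to an image: ``n x h x w`` stack."""
    if E.k != renderer.G.shape[0]:
        raise ValidationError(
            f"renderer expects {renderer.G.shape[0]}-dim embeddings, got {E.k}"
        )
    flat = E.E @ renderer.G
    return flat.reshape(-1, renderer.height, renderer.width)


# ---------------------------------------------------------------------------
# serialization


def save_decoder(path: str | Path, dec: LinearDecoder) -> None:
    np.savez(path, B=dec.B, intercept=dec.intercept, alpha=np.asarray(dec.alpha))


def load_decoder(path: str | Path) -> LinearDecoder:
    with np.load(path, allow_pickle=False) as npz:
        return LinearDecoder(
            B=npz["B"], intercept=npz["intercept"], alpha=float(npz["alpha"])
        )


def save_renderer(path: str | Path, r: ImageRenderer) -> None:
    np.savez(
        path,
        G=r.G,
        height=np.asarray(r.height),
        width=np.asarray(r.width),
        seed=np.asarray(r.seed),
    )


def load_renderer(path: str | Path) -> ImageRenderer:
    with np.load(path, allow_pickle=False) as npz:
        return ImageRenderer(
            G=npz["G"],
            height=int(npz["height"]),
            width=int(npz["width"]),
            seed=int(npz["seed"]),
        )


def save_embeddings(path: str | Path, E: StimulusEmbeddings) -> None:
    np.savez(path, E=E.E, stimulus_ids=E.stimulus_ids)


def load_embeddings(path: str | Path) -> StimulusEmbeddings:
    with np.load(path, allow_pickle=False) as npz:
        return StimulusEmbeddings(npz["stimulus_ids"], npz["E"])
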