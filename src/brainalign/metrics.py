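"""Reconstruction and identification metrics.

* ``pixcorr`` — mean per-item Pearson correlation between flattened
  predicted and ground-truth images.
* ``ssim`` — mean structural similarity (Gaussian window 11, sigma 1.5).
* ``two_way_accuracy`` — pairwise 2-way identification: over every
  ordered pair of distinct test items ``(i, j)``, a trial is correct when
  the predicted representation of item ``i`` is more similar to its own
  ground truth than to item ``j``'s.  Applied to regressed embeddings it
  is the "direct" identification score; applied to features of rendered
  images it mirrors feature-space identification.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable

import numpy as np
from skimage.metrics import structural_similarity

from .data import ValidationError


@dataclasses.dataclass
class MetricsReport:
    """Metric values for one evaluation cell."""

    pixcorr: float | None = None
    ssim: float | None = None
    two_way: dict[str, float] = dataclasses.field(default_factory=dict)
    n_items: int = 0

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.pixcorr is not None:
            out["pixcorr"] = self.pixcorr
        if self.ssim is not None:
            out["ssim"] = self.ssim
        for name, acc in self.two_way.items():
            out[f"two_way_{name}"] = acc
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({**self.as_dict(), "n_items": self.n_items}, fh, indent=2)


def _flatten_stack(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    return images.reshape(images.shape[0], -1)


def pixcorr(pred_images: np.ndarray, true_images: np.ndarray) -> float:
    """Mean Pearson correlation of flattened pixels, one value per item.

    An item where either image has zero pixel variance scores 0 and a
    warning is issued.
    """
    P = _flatten_stack(pred_images)
    T = _flatten_stack(true_images)
    if P.shape != T.shape:
        raise ValidationError("predicted and true image stacks differ in shape")
    Pc = P - P.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(Pc, axis=1)
    tn = np.linalg.norm(Tc, axis=1)
    bad = (pn == 0) | (tn == 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance image(s) scored as 0 in pixcorr",
            stacklevel=2,
        )
    denom = np.where(bad, 1.0, pn * tn)
    r = np.where(bad, 0.0, (Pc * Tc).sum(axis=1) / denom)
    return float(r.mean())


def ssim(
    pred_images: np.ndarray,
    true_images: np.ndarray,
    dynamic_range: float | None = None,
    use_global_stats: bool = False,
) -> float:
    """Mean structural similarity over an image stack.

    Windowed SSIM uses a Gaussian window of size 11 with sigma 1.5 and the
    population (not sample) covariance, with stabilizers
    ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2`` for dynamic range ``L``.
    ``dynamic_range`` defaults to the observed max minus min of the true
    images (synthetic stacks are not 8-bit).  Images smaller than the
    window require ``use_global_stats``, which evaluates the same formula
    once on whole-image statistics.
    """
    pred = np.asarray(pred_images, dtype=np.float64)
    true = np.asarray(true_images, dtype=np.float64)
    if pred.ndim == 2:
        pred, true = pred[None], true[None]
    if pred.shape != true.shape:
        raise ValidationError("predicted and true image stacks differ in shape")
    if dynamic_range is None:
        dynamic_range = float(true.max() - true.min())
        if dynamic_range == 0.0:
            dynamic_range = 1.0
    if dynamic_range <= 0:
        raise ValidationError("dynamic_range must be positive")

    if use_global_stats:
        vals = [_global_ssim(p, t, dynamic_range) for p, t in zip(pred, true)]
        return float(np.mean(vals))

    if min(pred.shape[1], pred.shape[2]) < 11:
        raise ValidationError(
            "images smaller than the 11-pixel SSIM window; "
            "pass use_global_stats=True for a whole-image fallback"
        )
    vals = [
        structural_similarity(
            t,
            p,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=dynamic_range,
        )
        for p, t in zip(pred, true)
    ]
    return float(np.mean(vals))


def _global_ssim(p: np.ndarray, t: np.ndarray, L: float) -> float:
    """SSIM formula on whole-image mean/variance/covariance."""
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mp, mt = p.mean(), t.mean()
    vp, vt = p.var(), t.var()
    cov = ((p - mp) * (t - mt)).mean()
    return float(
        ((2 * mp * mt + c1) * (2 * cov + c2))
        / ((mp**2 + mt**2 + c1) * (vp + vt + c2))
    )


def _similarity_matrix(P: np.ndarray, T: np.ndarray, similarity: str) -> np.ndarray:
    """``M[i, j] = sim(pred_i, true_j)`` for Pearson or cosine similarity."""
    if similarity == "pearson":
        P = P - P.mean(axis=1, keepdims=True)
        T = T - T.mean(axis=1, keepdims=True)
    elif similarity != "cosine":
        raise ValidationError(f"unknown similarity {similarity!r}")
    pn = np.linalg.norm(P, axis=1, keepdims=True)
    tn = np.linalg.norm(T, axis=1, keepdims=True)
    pn[pn == 0] = 1.0
    tn[tn == 0] = 1.0
    return (P / pn) @ (T / tn).T


def two_way_accuracy(
    pred_feats: np.ndarray, true_feats: np.ndarray, similarity: str = "pearson"
) -> float:
    """Exhaustive pairwise 2-way identification accuracy.

    All ``n (n - 1)`` ordered pairs of distinct items are scored; a trial
    where ``sim(pred_i, true_i) > sim(pred_i, true_j)`` counts 1, a tie
    counts 0.5.  Chance level is 0.5 for predictions independent of the
    truth.
    """
    P = np.asarray(pred_feats, dtype=np.float64)
    T = np.asarray(true_feats, dtype=np.float64)
    P = P.reshape(P.shape[0], -1)
    T = T.reshape(T.shape[0], -1)
    if P.shape != T.shape:
        raise ValidationError("predicted and true feature matrices differ in shape")
    n = P.shape[0]
    if n < 2:
        raise ValidationError("2-way identification needs at least 2 items")
    M = _similarity_matrix(P, T, similarity)
    d = np.diag(M)[:, None]
    wins = (d > M).astype(np.float64) + 0.5 * (d == M)
    off = ~np.eye(n, dtype=bool)
    return float(wins[off].mean())


# ---------------------------------------------------------------------------
# pluggable feature extractors for feature-space identification

FeatureExtractor = Callable[[np.ndarray], np.ndarray]


def pixel_features(images: np.ndarray) -> np.ndarray:
    """Identity extractor: flattened pixels."""
    return _flatten_stack(images)


def random_projection_features(n_features: int = 64, seed: int = 0) -> FeatureExtractor:
    """A fixed seeded linear projection of pixels, as a stand-in feature
    space slot-compatible with pretrained-network extractors."""
    cache: dict[int, np.ndarray] = {}

    def extract(images: np.ndarray) -> np.ndarray:
        flat = _flatten_stack(images)
        d = flat.shape[1]
        if d not in cache:
            cache[d] = np.random.default_rng(seed).standard_normal((d, n_features))
        return flat @ cache[d]

    return extract


def evaluate_reconstruction(
    pred_images: np.ndarray,
    true_images: np.ndarray,
    pred_embeddings: np.ndarray | None = None,
    true_embeddings: np.ndarray | None = None,
    extractors: dict[str, FeatureExtractor] | None = None,
    similarity: str = "pearson",
) -> MetricsReport:
    """Compute the full metric suite for one set of reconstructions."""
    report = MetricsReport(
        pixcorr=pixcorr(pred_images, true_images),
        ssim=ssim(pred_images, true_images),
        n_items=int(np.asarray(true_images).shape[0]),
    )
    if extractors is None:
        extractors = {"pixels": pixel_features}
    for name, fx in extractors.items():
        report.two_way[name] = two_way_accuracy(
            fx(pred_images), fx(true_images), similarity=similarity
        )
    if pred_embeddings is not None and true_embeddings is not None:
        report.two_way["direct"] = two_way_accuracy(
            pred_embeddings, true_embeddings, similarity=similarity
        )
    return report
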