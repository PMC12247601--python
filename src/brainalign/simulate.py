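"""Synthetic multi-subject datasets with known generative structure.

The generator emulates the statistical premise of functional alignment:
each stimulus has a latent embedding, each subject's voxel responses are
a linear mixing of that embedding plus Gaussian noise, and the two
subjects' voxel spaces are related by a known transform.  Two subjects
share a block of "common" stimuli (the alignment set) and each also sees
a disjoint block of subject-unique stimuli (used to train the decoder),
mirroring a shared-plus-unique stimulus design.

Modes control the source-target relation:

* ``orthogonal`` — the source is a rotated and rescaled copy of the
  target's clean signal (``target ~= c0 * source @ R0``), the regime
  scaled Procrustes assumes;
* ``linear`` — an arbitrary invertible linear map, the regime ridge
  alignment assumes;
* ``independent_mixing`` — each subject mixes the latent code through its
  own random matrix; no direct voxel correspondence, but a linear map
  still exists through the latent space;
* ``permuted_voxels`` — identical functional content at shuffled voxel
  locations: anatomically aligned (same grid) yet functionally scrambled,
  the regime where an identity baseline must fail and a learned map must
  succeed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from .data import ResponseMatrix, ValidationError, read_matrix, write_matrix
from .decoding import (
    ImageRenderer,
    StimulusEmbeddings,
    load_embeddings,
    load_renderer,
    render_images,
    save_embeddings,
    save_renderer,
)

MODES = ("orthogonal", "linear", "independent_mixing", "permuted_voxels")


@dataclasses.dataclass
class SyntheticConfig:
    """Generative settings for a paired-subject dataset.

    Defaults give each subject 1,200 stimuli of which 400 are common, a
    10-dimensional latent code mixed into 60 voxels, and response noise
    with standard deviation 0.5 (the latent code is unit-variance, so the
    clean voxel signal has standard deviation near ``sqrt(k)``).
    """

    n_stimuli: int = 1200
    n_common: int = 400
    k: int = 10
    v: int = 60
    noise_sd: float = 0.5
    mode: str = "orthogonal"
    seed: int = 0
    image_h: int = 16
    image_w: int = 16
    c0: float = 1.7  # scale of the orthogonal mode's ground-truth transform

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_common < 4:
            raise ValidationError("n_common must be at least 4")
        if self.n_common > self.n_stimuli:
            raise ValidationError("n_common cannot exceed n_stimuli")
        if self.k > self.v:
            raise ValidationError("latent dimension k cannot exceed voxel count v")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.c0 <= 0:
            raise ValidationError("c0 must be positive")


@dataclasses.dataclass
class SyntheticDataset:
    """A generated pair of subjects plus full ground truth."""

    target: ResponseMatrix
    source: ResponseMatrix
    embeddings: StimulusEmbeddings  # ground-truth E for every stimulus
    images: np.ndarray  # rendered ground-truth stimuli, n x h x w
    renderer: ImageRenderer
    truth: dict[str, Any]
    config: SyntheticConfig | None = None

    @property
    def common_ids(self) -> np.ndarray:
        return np.intersect1d(self.target.stimulus_ids, self.source.stimulus_ids)


def _random_orthogonal(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormalize a Gaussian matrix; any orthogonal matrix will do."""
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


def generate_multisubject(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a paired-subject dataset under the configured mode.

    Fully reproducible: every random draw (latent code, mixing matrices,
    transforms, noise, renderer) derives from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(5)
    rng_latent = np.random.default_rng(child[0])
    rng_mix = np.random.default_rng(child[1])
    rng_map = np.random.default_rng(child[2])
    rng_noise = np.random.default_rng(child[3])
    render_seed = int(child[4].generate_state(1)[0] % (2**31))

    n_unique = config.n_stimuli - config.n_common
    common_ids = np.array([f"c{i:06d}" for i in range(config.n_common)])
    tgt_unique = np.array([f"u_tgt{i:06d}" for i in range(n_unique)])
    src_unique = np.array([f"u_src{i:06d}" for i in range(n_unique)])
    all_ids = np.concatenate([common_ids, src_unique, tgt_unique])
    all_ids = np.sort(all_ids)  # common ids sort first ('c' < 'u')
    id_pos = {sid: i for i, sid in enumerate(all_ids.tolist())}

    n_total = len(all_ids)
    E = rng_latent.standard_normal((n_total, config.k))
    A = rng_mix.standard_normal((config.k, config.v))
    clean = E @ A  # clean target-space signal for every stimulus

    tgt_ids = np.sort(np.concatenate([common_ids, tgt_unique]))
    src_ids = np.sort(np.concatenate([common_ids, src_unique]))
    tgt_rows = np.array([id_pos[s] for s in tgt_ids.tolist()])
    src_rows = np.array([id_pos[s] for s in src_ids.tolist()])

    truth: dict[str, Any] = {"A": A, "mode": config.mode}
    if config.mode == "orthogonal":
        R0 = _random_orthogonal(config.v, rng_map)
        truth["R0"], truth["c0"] = R0, config.c0
        src_clean = (1.0 / config.c0) * clean[src_rows] @ R0.T
    elif config.mode == "linear":
        M = rng_map.standard_normal((config.v, config.v)) + np.eye(config.v)
        truth["M"] = M
        src_clean = clean[src_rows] @ M
    elif config.mode == "independent_mixing":
        A_S = rng_map.standard_normal((config.k, config.v))
        truth["A_S"] = A_S
        src_clean = E[src_rows] @ A_S
    else:  # permuted_voxels
        perm = rng_map.permutation(config.v)
        truth["perm"] = perm
        src_clean = clean[src_rows][:, perm]

    tgt = clean[tgt_rows] + config.noise_sd * rng_noise.standard_normal(
        (len(tgt_rows), config.v)
    )
    src = src_clean + config.noise_sd * rng_noise.standard_normal(
        (len(src_rows), config.v)
    )

    renderer = ImageRenderer.create(
        config.k, config.image_h, config.image_w, seed=render_seed
    )
    embeddings = StimulusEmbeddings(all_ids, E)
    images = render_images(embeddings, renderer)

    return SyntheticDataset(
        target=ResponseMatrix("target", tgt_ids, tgt),
        source=ResponseMatrix("source", src_ids, src),
        embeddings=embeddings,
        images=images,
        renderer=renderer,
        truth=truth,
        config=config,
    )


def save_dataset(directory: str | Path, ds: SyntheticDataset) -> None:
    """Write a dataset as container files plus a ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(directory / "target.npz", ds.target)
    write_matrix(directory / "source.npz", ds.source)
    save_embeddings(directory / "embeddings.npz", ds.embeddings)
    save_renderer(directory / "renderer.npz", ds.renderer)
    arrays = {k: np.asarray(v) for k, v in ds.truth.items() if k != "mode"}
    np.savez(directory / "truth.npz", **arrays)
    sidecar = {"mode": ds.truth.get("mode"), "truth_arrays": sorted(arrays)}
    if ds.config is not None:
        sidecar["config"] = dataclasses.asdict(ds.config)
    with open(directory / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Load a dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    target = read_matrix(directory / "target.npz")
    source = read_matrix(directory / "source.npz")
    embeddings = load_embeddings(directory / "embeddings.npz")
    renderer = load_renderer(directory / "renderer.npz")
    with open(directory / "truth.json") as fh:
        sidecar = json.load(fh)
    truth: dict[str, Any] = {"mode": sidecar.get("mode")}
    with np.load(directory / "truth.npz", allow_pickle=False) as npz:
        for key in npz.files:
            truth[key] = npz[key]
    config = None
    if "config" in sidecar:
        config = SyntheticConfig(**sidecar["config"])
    return SyntheticDataset(
        target=target,
        source=source,
        embeddings=embeddings,
        images=render_images(embeddings, renderer),
        renderer=renderer,
        truth=truth,
        config=config,
    )
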