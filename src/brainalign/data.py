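"""Containers and bookkeeping for stimulus-evoked fMRI response matrices.

A *response matrix* holds one subject's GLM beta coefficients as a
``(n_stimuli, n_voxels)`` array together with the stimulus identifiers
labelling its rows.  Cross-subject functional alignment operates on the
rows evoked by stimuli that two subjects have both seen; the bookkeeping
here (repeat averaging, common-stimulus matching, ROI masking) turns raw
per-subject data into the row-matched matrix pairs the estimators consume.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


def order_ids(ids: np.ndarray) -> np.ndarray:
    """Return the indices sorting stimulus ids deterministically.

    String ids sort lexicographically ascending, integer ids numerically
    ascending.  Every operation that must pick a canonical row order
    (matching, repeat averaging) routes through this rule.
    """
    ids = np.asarray(ids)
    return np.argsort(ids, kind="stable")


def _as_id_array(ids: Sequence) -> np.ndarray:
    arr = np.asarray(ids)
    if arr.ndim != 1:
        raise ValidationError("stimulus_ids must be one-dimensional")
    if arr.dtype.kind not in "USiu":
        arr = arr.astype(str)
    return arr


@dataclasses.dataclass
class ResponseMatrix:
    """One subject's beta coefficients: ``n`` stimuli by ``v`` voxels.

    Parameters
    ----------
    subject_id:
        Label for the subject the betas belong to.
    stimulus_ids:
        Unique identifiers for the rows, length ``n``.
    betas:
        Real matrix of GLM coefficients, shape ``(n, v)``, unitless.
    """

    subject_id: str
    stimulus_ids: np.ndarray
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.stimulus_ids = _as_id_array(self.stimulus_ids)
        self.betas = np.asarray(self.betas, dtype=np.float64)
        if self.betas.ndim != 2:
            raise ValidationError("betas must be a 2-D (stimuli x voxels) array")
        if self.betas.shape[0] != self.stimulus_ids.shape[0]:
            raise ValidationError(
                f"betas has {self.betas.shape[0]} rows but stimulus_ids has "
                f"{self.stimulus_ids.shape[0]} entries"
            )
        if len(np.unique(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValidationError("stimulus_ids contains duplicates")
        if not np.all(np.isfinite(self.betas)):
            raise ValidationError("betas contains non-finite values")

    @property
    def n_stimuli(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def subset(self, ids: Iterable) -> "ResponseMatrix":
        """Rows for the given ids, in the order given."""
        ids = np.asarray(list(ids))
        pos = {sid: i for i, sid in enumerate(self.stimulus_ids.tolist())}
        try:
            rows = [pos[sid] for sid in ids.tolist()]
        except KeyError as exc:
            raise ValidationError(f"unknown stimulus id {exc.args[0]!r}") from exc
        return ResponseMatrix(self.subject_id, ids, self.betas[rows])


@dataclasses.dataclass
class CommonPair:
    """Row-matched source/target response matrices over shared stimuli."""

    source: ResponseMatrix
    target: ResponseMatrix

    def __post_init__(self) -> None:
        if not np.array_equal(self.source.stimulus_ids, self.target.stimulus_ids):
            raise ValidationError("source and target stimulus_ids differ")
        if self.source.n_stimuli < 2:
            raise ValidationError("a common pair needs at least 2 matched rows")

    @property
    def stimulus_ids(self) -> np.ndarray:
        return self.source.stimulus_ids

    @property
    def n_stimuli(self) -> int:
        return self.source.n_stimuli


@dataclasses.dataclass
class RoiMask:
    """Binary 3-D region-of-interest mask with a fixed linearization.

    Voxels are linearized in C order over axes ``(x, y, z)`` — the last
    axis varies fastest, the first slowest.  Column ``j`` of any matrix
    extracted through this mask is the ``j``-th true voxel in that order.
    """

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be 3-D")
        if not self.voxels.any():
            raise ValidationError("mask selects no voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def linear_indices(self) -> np.ndarray:
        """Strictly increasing flat (C-order) indices of the true voxels."""
        return np.flatnonzero(self.voxels.ravel(order="C"))


# ---------------------------------------------------------------------------
# container I/O


def write_matrix(path: str | Path, rm: ResponseMatrix) -> None:
    """Write a response matrix to a single-file ``.npz`` container.

    Arrays stored: ``betas`` (float64), ``stimulus_ids``, ``subject_id``.
    """
    np.savez(
        path,
        betas=rm.betas,
        stimulus_ids=rm.stimulus_ids,
        subject_id=np.asarray(rm.subject_id),
    )


def read_matrix(path: str | Path) -> ResponseMatrix:
    """Read a response matrix written by :func:`write_matrix`.

    Raises :class:`ValidationError` naming the missing or malformed field.
    """
    with np.load(path, allow_pickle=False) as npz:
        for key in ("betas", "stimulus_ids", "subject_id"):
            if key not in npz:
                raise ValidationError(f"container is missing array {key!r}")
        betas = npz["betas"]
        ids = npz["stimulus_ids"]
        subject_id = str(npz["subject_id"])
    return ResponseMatrix(subject_id, ids, betas)


def write_ids_csv(path: str | Path, rm: ResponseMatrix) -> None:
    """Export the stimulus ids as a one-column CSV."""
    with open(path, "w") as fh:
        fh.write("stimulus_id\n")
        for sid in rm.stimulus_ids.tolist():
            fh.write(f"{sid}\n")


# ---------------------------------------------------------------------------
# bookkeeping operations


def average_repeats(
    subject_id: str, stimulus_ids: Sequence, betas: np.ndarray
) -> ResponseMatrix:
    """Average the rows of repeated stimulus presentations.

    Returns one row per unique id (the arithmetic mean over its repeats),
    rows ordered by the deterministic id ordering.
    """
    ids = _as_id_array(stimulus_ids)
    betas = np.asarray(betas, dtype=np.float64)
    if betas.ndim != 2 or betas.shape[0] != ids.shape[0]:
        raise ValidationError("betas rows must match stimulus_ids length")
    if ids.shape[0] == 0:
        raise ValidationError("cannot average an empty set of rows")
    unique_ids, inverse = np.unique(ids, return_inverse=True)
    sums = np.zeros((len(unique_ids), betas.shape[1]))
    np.add.at(sums, inverse, betas)
    counts = np.bincount(inverse, minlength=len(unique_ids))
    return ResponseMatrix(subject_id, unique_ids, sums / counts[:, None])


def match_common(
    source: ResponseMatrix,
    target: ResponseMatrix,
    exclude_ids: Iterable | None = None,
) -> CommonPair:
    """Row-match two subjects over their shared stimuli.

    The pair contains exactly the intersection of the two id sets, minus
    ``exclude_ids`` (e.g. a visual hold-out reserved for qualitative
    inspection), in deterministic sorted order.
    """
    common = np.intersect1d(source.stimulus_ids, target.stimulus_ids)
    if exclude_ids is not None:
        excl = _as_id_array(np.asarray(list(exclude_ids)))
        common = np.setdiff1d(common, excl)
    if len(common) < 2:
        raise ValidationError("insufficient common stimuli (need at least 2)")
    return CommonPair(source.subset(common), target.subset(common))


def mask_volumes(
    volumes: np.ndarray, mask: RoiMask, ids: Sequence, subject_id: str = ""
) -> ResponseMatrix:
    """Reduce a 4-D beta image ``(x, y, z, stimuli)`` to a response matrix.

    One output column per true mask voxel, columns in the mask's fixed
    linearization order (C order over ``(x, y, z)``).
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    if volumes.ndim != 4:
        raise ValidationError("volumes must be 4-D (x, y, z, stimuli)")
    if volumes.shape[:3] != mask.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume spatial shape "
            f"{volumes.shape[:3]}"
        )
    n = volumes.shape[3]
    flat = np.ascontiguousarray(volumes).reshape(-1, n)
    betas = flat[mask.linear_indices()].T
    return ResponseMatrix(subject_id, np.asarray(ids), betas)


def scatter_to_volumes(rm: ResponseMatrix, mask: RoiMask) -> np.ndarray:
    """Inverse of :func:`mask_volumes`: place columns back into a 4-D volume.

    Voxels outside the mask are zero.
    """
    n = rm.n_stimuli
    flat = np.zeros((int(np.prod(mask.shape)), n))
    flat[mask.linear_indices()] = rm.betas.T
    return flat.reshape(*mask.shape, n)


def load_nifti_volumes(
    volume_path: str | Path, mask_path: str | Path, ids: Sequence, subject_id: str = ""
) -> ResponseMatrix:
    """Load a 4-D NIfTI beta image and a binary NIfTI mask, then extract."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(volume_path)).dataobj)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj)
    return mask_volumes(vol, RoiMask(mask > 0), ids, subject_id=subject_id)
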