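"""Experimental designs: fraction sweeps, all-pairs grids, pseudo-common sets.

``run_fraction_sweep`` measures how decoding quality depends on the amount
of shared data used to fit the alignment: for each alignment method and
each fraction of the common stimulus set, it fits the alignment on a
seeded subsample, transfers the source subject's held-out responses into
the target space, decodes them with the target-trained decoder, and
scores the reconstructions.  The within-subject ceiling (the target
decoded on its own responses) provides the upper baseline.

``run_pair_grid`` runs every source x target combination of a cohort;
diagonal cells are within-subject decoding, off-diagonal cells are
cross-subject decoding through a fitted alignment.

``build_pseudo_common_set`` supports cross-dataset alignment when no
stimuli are literally shared: it pairs up semantically similar stimuli by
greedy nearest-neighbor matching on embeddings, producing a surrogate
common set.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import (
    DEFAULT_ALPHA_GRID,
    apply_alignment,
    fit_anatomical,
    fit_procrustes,
    fit_ridge_alignment,
    subsample_alignment_set,
)
from .data import CommonPair, ResponseMatrix, ValidationError, match_common
from .decoding import (
    StimulusEmbeddings,
    fit_linear_decoder,
    predict_embeddings,
    render_images,
)
from .metrics import pixcorr, ssim, two_way_accuracy
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)

METHODS = ("anatomical", "procrustes", "ridge")


@dataclasses.dataclass
class SweepConfig:
    """Design of a shared-data-fraction sweep.

    ``fractions`` are proportions of the common set used to fit the
    alignment; ``n_seeds`` replicates the subsampling.  ``strict_test``
    reserves a disjoint quarter of the common set for evaluation at every
    fraction; by default the test set is the common rows left unused by
    the alignment subsample, and at fraction 1.0 the full common set
    (which also trained the alignment — the trade-off of evaluating on
    shared stimuli when no other labeled rows exist for the source).
    """

    fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 1.00)
    methods: tuple[str, ...] = METHODS
    n_seeds: int = 10
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_folds: int = 5
    seed: int = 0
    decoder_alpha: float = 10.0
    similarity: str = "pearson"
    include_pixel_metrics: bool = True
    strict_test: bool = False
    exclude_ids: tuple | None = None

    def __post_init__(self) -> None:
        if list(self.fractions) != sorted(self.fractions):
            raise ValidationError("fractions must be sorted ascending")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValidationError("fractions must lie in (0, 1]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown methods {sorted(unknown)}")
        if self.n_seeds < 1:
            raise ValidationError("n_seeds must be positive")


@dataclasses.dataclass
class SweepResult:
    """Long-format sweep records: method, fraction, seed, metric, value.

    The within-subject ceiling appears as method ``within_subject`` with
    fraction 1.0 and seed -1.
    """

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean and sd of each metric per method x fraction."""
        return (
            self.records.groupby(["method", "fraction", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _fit_method(method: str, pair: CommonPair, cfg: SweepConfig, seed: int):
    if method == "anatomical":
        return fit_anatomical(pair)
    if method == "procrustes":
        return fit_procrustes(pair)
    if method == "ridge":
        return fit_ridge_alignment(
            pair, alpha_grid=cfg.alpha_grid, n_folds=cfg.n_folds, seed=seed
        )
    raise ValidationError(f"unknown method {method!r}")


def _cell_metrics(
    pred_emb: StimulusEmbeddings,
    true_emb: StimulusEmbeddings,
    data: SyntheticDataset,
    cfg: SweepConfig,
) -> dict[str, float]:
    out = {
        "two_way_direct": two_way_accuracy(
            pred_emb.E, true_emb.E, similarity=cfg.similarity
        )
    }
    if cfg.include_pixel_metrics:
        pred_img = render_images(pred_emb, data.renderer)
        true_img = render_images(true_emb, data.renderer)
        out["pixcorr"] = pixcorr(pred_img, true_img)
        out["ssim"] = ssim(pred_img, true_img)
        out["two_way_pixels"] = two_way_accuracy(
            pred_img, true_img, similarity=cfg.similarity
        )
    return out


def run_fraction_sweep(data: SyntheticDataset, cfg: SweepConfig) -> SweepResult:
    """Run the alignment-method x common-fraction x seed sweep.

    The decoder is trained once, on the target subject's non-common rows
    only; its training ids are asserted disjoint from every cell's test
    ids.  Each cell is deterministic given its seed.  A cell whose fit
    fails is recorded with a NaN value and logged rather than aborting
    the sweep.
    """
    target, source = data.target, data.source
    common_ids = np.intersect1d(target.stimulus_ids, source.stimulus_ids)
    decoder_train_ids = np.setdiff1d(target.stimulus_ids, common_ids)
    if len(decoder_train_ids) < 2:
        raise ValidationError("target subject has no non-common rows to train on")
    decoder = fit_linear_decoder(
        target.subset(decoder_train_ids),
        data.embeddings.subset(decoder_train_ids),
        alpha=cfg.decoder_alpha,
    )
    pair = match_common(source, target, exclude_ids=cfg.exclude_ids)
    full_ids = pair.stimulus_ids
    train_id_set = set(decoder_train_ids.tolist())

    strict_test_ids: np.ndarray | None = None
    align_pool = pair
    if cfg.strict_test:
        rng = np.random.default_rng(cfg.seed)
        n_test = max(2, len(full_ids) // 4)
        strict_test_ids = np.sort(rng.permutation(full_ids)[:n_test])
        pool_ids = np.setdiff1d(full_ids, strict_test_ids)
        align_pool = CommonPair(
            pair.source.subset(pool_ids), pair.target.subset(pool_ids)
        )

    rows: list[dict] = []

    def record(method: str, fraction: float, seed: int, metrics: dict[str, float]):
        for name, value in metrics.items():
            rows.append(
                {
                    "method": method,
                    "fraction": fraction,
                    "seed": seed,
                    "metric": name,
                    "value": value,
                }
            )

    for rep in range(cfg.n_seeds):
        rep_seed = cfg.seed + rep
        for fraction in cfg.fractions:
            try:
                sub = subsample_alignment_set(align_pool, fraction, seed=rep_seed)
                if strict_test_ids is not None:
                    test_ids = strict_test_ids
                elif fraction == 1.0:
                    test_ids = full_ids
                else:
                    test_ids = np.setdiff1d(full_ids, sub.stimulus_ids)
                assert not train_id_set.intersection(test_ids.tolist()), (
                    "decoder training ids leaked into the test set"
                )
                true_emb = data.embeddings.subset(test_ids)
                for method in cfg.methods:
                    try:
                        model = _fit_method(method, sub, cfg, rep_seed)
                        aligned = apply_alignment(model, source.subset(test_ids))
                        pred_emb = predict_embeddings(decoder, aligned)
                        metrics = _cell_metrics(pred_emb, true_emb, data, cfg)
                        if method == "ridge":
                            logger.info(
                                "ridge cell fraction=%.2f seed=%d alpha=%g",
                                fraction,
                                rep_seed,
                                model.alpha,
                            )
                        record(method, fraction, rep_seed, metrics)
                    except (ValidationError, np.linalg.LinAlgError) as exc:
                        logger.warning(
                            "cell failed: method=%s fraction=%.2f seed=%d: %s",
                            method,
                            fraction,
                            rep_seed,
                            exc,
                        )
                        record(method, fraction, rep_seed, {"error": np.nan})
            except ValidationError as exc:
                logger.warning(
                    "fraction %.2f unusable at seed %d: %s", fraction, rep_seed, exc
                )
                for method in cfg.methods:
                    record(method, fraction, rep_seed, {"error": np.nan})

    # within-subject ceiling: the target decoded on its own test rows
    ceiling_ids = strict_test_ids if strict_test_ids is not None else full_ids
    ceil_pred = predict_embeddings(decoder, target.subset(ceiling_ids))
    ceil_metrics = _cell_metrics(
        ceil_pred, data.embeddings.subset(ceiling_ids), data, cfg
    )
    record("within_subject", 1.0, -1, ceil_metrics)

    return SweepResult(records=pd.DataFrame(rows))


def run_pair_grid(
    subjects: Sequence[ResponseMatrix],
    embeddings: StimulusEmbeddings,
    methods: Sequence[str] = METHODS,
    common_ids: np.ndarray | None = None,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    decoder_alpha: float = 10.0,
    similarity: str = "pearson",
) -> dict[str, pd.DataFrame]:
    """Direct 2-way identification for every source x target combination.

    Diagonal cells decode a subject with its own decoder; off-diagonal
    cells align the source's common rows to the target's space and decode
    with the target's decoder.  Returns one source-by-target DataFrame
    per method.
    """
    if len(subjects) < 2:
        raise ValidationError("pair grid needs at least 2 subjects")
    ids_list = [s.stimulus_ids for s in subjects]
    shared = ids_list[0]
    for ids in ids_list[1:]:
        shared = np.intersect1d(shared, ids)
    if common_ids is None:
        common_ids = shared
    else:
        common_ids = np.intersect1d(np.asarray(common_ids), shared)
    if len(common_ids) < 2:
        raise ValidationError("subjects share fewer than 2 common stimuli")

    decoders = []
    for subj in subjects:
        train_ids = np.setdiff1d(subj.stimulus_ids, common_ids)
        if len(train_ids) < 2:
            raise ValidationError(
                f"subject {subj.subject_id!r} has no non-common rows to train on"
            )
        decoders.append(
            fit_linear_decoder(
                subj.subset(train_ids),
                embeddings.subset(train_ids),
                alpha=decoder_alpha,
            )
        )

    true_emb = embeddings.subset(common_ids)
    labels = [s.subject_id for s in subjects]
    grids = {
        m: pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
        for m in methods
    }
    for i, src in enumerate(subjects):  # source rows
        for j, tgt in enumerate(subjects):  # target columns
            if i == j:
                pred = predict_embeddings(decoders[j], tgt.subset(common_ids))
                acc = two_way_accuracy(pred.E, true_emb.E, similarity=similarity)
                for m in methods:
                    grids[m].iloc[i, j] = acc
                continue
            pair = CommonPair(src.subset(common_ids), tgt.subset(common_ids))
            for m in methods:
                try:
                    if m == "anatomical":
                        model = fit_anatomical(pair)
                    elif m == "procrustes":
                        model = fit_procrustes(pair)
                    else:
                        model = fit_ridge_alignment(
                            pair, alpha_grid=alpha_grid, n_folds=n_folds, seed=seed
                        )
                    aligned = apply_alignment(model, src.subset(common_ids))
                    pred = predict_embeddings(decoders[j], aligned)
                    grids[m].iloc[i, j] = two_way_accuracy(
                        pred.E, true_emb.E, similarity=similarity
                    )
                except (ValidationError, np.linalg.LinAlgError) as exc:
                    logger.warning(
                        "grid cell failed: %s -> %s (%s): %s",
                        src.subject_id,
                        tgt.subject_id,
                        m,
                        exc,
                    )
    return grids


def build_pseudo_common_set(
    emb_a: StimulusEmbeddings,
    emb_b: StimulusEmbeddings,
    n_pairs: int,
    min_similarity: float = -1.0,
) -> list[tuple]:
    """Greedy one-to-one matching of semantically similar stimuli.

    All cross-set cosine similarities are ranked descending; pairs are
    accepted greedily, each stimulus used at most once, stopping after
    ``n_pairs`` pairs or when similarity drops below ``min_similarity``.
    Returns ``(id_a, id_b)`` tuples in acceptance order.
    """
    if n_pairs < 2:
        raise ValidationError("n_pairs must be at least 2")
    if emb_a.E.shape[0] == 0 or emb_b.E.shape[0] == 0:
        raise ValidationError("embedding sets must be nonempty")
    A = emb_a.E / np.maximum(np.linalg.norm(emb_a.E, axis=1, keepdims=True), 1e-300)
    B = emb_b.E / np.maximum(np.linalg.norm(emb_b.E, axis=1, keepdims=True), 1e-300)
    sim = A @ B.T
    order = np.argsort(sim, axis=None)[::-1]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple] = []
    for flat in order:
        ia, ib = np.unravel_index(flat, sim.shape)
        if sim[ia, ib] < min_similarity or len(pairs) >= n_pairs:
            break
        if ia in used_a or ib in used_b:
            continue
        used_a.add(int(ia))
        used_b.add(int(ib))
        pairs.append(
            (emb_a.stimulus_ids[ia].item(), emb_b.stimulus_ids[ib].item())
        )
    if len(pairs) < 2:
        raise ValidationError(
            "fewer than 2 admissible pairs above the similarity threshold"
        )
    return pairs
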