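"""The patient-specific fine-tuning core: composite loss, pre-training, the
two per-patient schedules (cumulative "adaptive" and checkpoint-chained
"sequence"), and schedule evaluation.

Both schedules share one atom, the :class:`TrainTestStep`: fine-tune on a set
of past fractions, test on strictly later ones (no test fraction ever appears
in its own training set).  The adaptive schedule re-starts every step from
the generalized (pre-trained) checkpoint and grows the training set
cumulatively; the sequence schedule trains on exactly one new fraction per
step, chaining checkpoints so per-step cost stays constant.

An "epoch" of patch-based fine-tuning is defined as
``patches_per_volume_per_epoch`` seeded augmented patches drawn from each
training fraction.  Augmentation randomness is derived from (seed, patient,
step ordinal) so the first step of both schedules — same data, same
initialization — is bit-identical in deterministic mode, and any step can be
replayed in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .backbone import ReferenceNet, sliding_window_predict, softmax_scores
from .io import (
    CheckpointRef,
    checkpoint_filename,
    load_checkpoint,
    load_fraction,
    save_checkpoint,
)
from .metrics import dsc as _dsc
from .metrics import surface_distances
from .preprocess import PreprocessConfig, augment, clip_hu, normalize_intensity, resample
from .records import CohortManifest
from .volume import Volume

__all__ = [
    "TrainConfig",
    "TrainTestStep",
    "composite_loss",
    "composite_loss_with_grad",
    "pretrain",
    "fine_tune",
    "psn_adaptive_schedule",
    "psn_sequence_schedule",
    "run_schedule",
    "evaluate_schedule",
    "predict_mask",
]

_SMOOTH_EPS = 1e-5


@dataclass
class TrainConfig:
    """Optimization settings.

    Clinical-scale values (30 000 pre-training iterations, 96^3 crops) are
    configuration-reachable; the defaults here are desk-scale so the full
    two-stage pipeline runs on one CPU core in minutes.
    """

    lr: float = 1e-4
    weight_decay: float = 1e-5
    dice_weight: float = 0.5
    ce_weight: float = 0.5
    pretrain_iterations: int = 300
    pretrain_candidates: int = 1
    pretrain_max_candidates: int = 5
    pretrain_min_val_dsc: Optional[float] = None
    finetune_epochs: int = 50
    patches_per_volume_per_epoch: int = 4
    batch_size: int = 1
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if abs(self.dice_weight + self.ce_weight - 1.0) > 1e-12:
            raise ValueError("dice_weight + ce_weight must equal 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.finetune_epochs < 0 or self.pretrain_iterations < 0:
            raise ValueError("iteration/epoch counts must be >= 0")


@dataclass
class TrainTestStep:
    """One schedule atom: train on past fractions, test on future ones."""

    patient_id: str
    train_fractions: tuple[int, ...]
    test_fractions: tuple[int, ...]
    init: Optional[CheckpointRef] = None  # None = chained from previous step
    out: Optional[CheckpointRef] = None

    def __post_init__(self) -> None:
        self.train_fractions = tuple(sorted(int(f) for f in self.train_fractions))
        self.test_fractions = tuple(sorted(int(f) for f in self.test_fractions))
        if not self.train_fractions or not self.test_fractions:
            raise ValueError("train and test fraction sets must be nonempty")
        if set(self.train_fractions) & set(self.test_fractions):
            raise ValueError("train and test fraction sets must be disjoint")
        if max(self.train_fractions) >= min(self.test_fractions):
            raise ValueError(
                f"illegal step: max(train)={max(self.train_fractions)} must be < "
                f"min(test)={min(self.test_fractions)}"
            )


# ---------------------------------------------------------------------------
# Loss


def _check_target(target: np.ndarray) -> np.ndarray:
    t = np.asarray(target)
    if not np.all(np.isin(np.unique(t), (0, 1))):
        raise ValueError("target must be binary")
    return t.astype(np.float32)


def composite_loss_with_grad(
    scores: np.ndarray,
    target: np.ndarray,
    dice_weight: float = 0.5,
    ce_weight: float = 0.5,
) -> tuple[float, np.ndarray, float, float]:
    """Equal-weight soft-Dice + cross-entropy loss and its score gradient.

    Returns (total, d_total/d_scores, dice_term, ce_term) where the terms are
    the *unweighted* single-term losses, so the decomposition
    ``total = dice_weight * dice_term + ce_weight * ce_term`` is checkable.
    """
    t = _check_target(target)
    if scores.shape != (2, *t.shape):
        raise ValueError(f"scores shape {scores.shape} does not match target {t.shape}")
    p = softmax_scores(scores.astype(np.float32))
    n = t.size
    p1 = p[1].astype(np.float64)

    # Cross-entropy (mean over voxels).
    p_true = np.where(t > 0, p[1], p[0]).astype(np.float64)
    ce = float(-np.log(np.clip(p_true, 1e-12, None)).mean())
    g_ce = (p - np.stack([1.0 - t, t])) / n

    # Soft Dice on the target channel.
    inter = float((p1 * t).sum())
    denom = float(p1.sum() + t.sum()) + _SMOOTH_EPS
    dice_loss = 1.0 - (2.0 * inter + _SMOOTH_EPS) / denom
    dld_p1 = -(2.0 * t * denom - (2.0 * inter + _SMOOTH_EPS)) / denom**2
    g_z1 = dld_p1 * p1 * (1.0 - p1)
    g_dice = np.stack([-g_z1, g_z1])

    total = dice_weight * dice_loss + ce_weight * ce
    grad = (dice_weight * g_dice + ce_weight * g_ce).astype(np.float32)
    return total, grad, dice_loss, ce


def composite_loss(
    scores: np.ndarray,
    target: np.ndarray,
    dice_weight: float = 0.5,
    ce_weight: float = 0.5,
) -> float:
    """Scalar composite loss (see :func:`composite_loss_with_grad`)."""
    return composite_loss_with_grad(scores, target, dice_weight, ce_weight)[0]


# ---------------------------------------------------------------------------
# Data plumbing


def _prepared_fraction(
    manifest: CohortManifest, patient_id: str, fraction: int, pre_cfg: PreprocessConfig
) -> tuple[Volume, np.ndarray]:
    """Clipped + resampled (HU image, mask) pair ready for augmentation."""
    rec = load_fraction(manifest, manifest.entry(patient_id, fraction))
    img = clip_hu(rec.image, pre_cfg.hu_window)
    img = resample(img, pre_cfg.target_spacing_mm, is_mask=False)
    msk = resample(
        Volume(rec.ctv_mask, rec.image.spacing_mm, rec.image.origin_mm),
        pre_cfg.target_spacing_mm,
        is_mask=True,
    ).values
    return img, msk


def _train_patch(
    img: Volume,
    msk: np.ndarray,
    pre_cfg: PreprocessConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    aug_img, aug_msk = augment(img, msk, pre_cfg, rng)
    x = normalize_intensity(aug_img, pre_cfg.hu_window).values[None]
    return x, aug_msk


def _train_steps(
    model: ReferenceNet,
    pairs: Sequence[tuple[Volume, np.ndarray]],
    order: Sequence[int],
    cfg: TrainConfig,
    pre_cfg: PreprocessConfig,
    rng: np.random.Generator,
    optimizer,
) -> list[float]:
    """Run one optimizer step per drawn patch (batch accumulation if set)."""
    losses = []
    batch: list[tuple[np.ndarray, np.ndarray]] = []
    model.train()
    for idx in order:
        img, msk = pairs[idx]
        x, t = _train_patch(img, msk, pre_cfg, rng)
        batch.append((x, t))
        if len(batch) < max(1, cfg.batch_size):
            continue
        optimizer.zero_grad()
        total = 0.0
        for bx, bt in batch:
            scores = model.forward(bx)
            loss, grad, _, _ = composite_loss_with_grad(
                scores, bt, cfg.dice_weight, cfg.ce_weight
            )
            model.backward(grad / len(batch))
            total += loss / len(batch)
        optimizer.step()
        losses.append(total)
        batch = []
    return losses


# ---------------------------------------------------------------------------
# Stage 1: cohort pre-training


def pretrain(
    manifest: CohortManifest,
    model: ReferenceNet,
    cfg: TrainConfig,
    pre_cfg: PreprocessConfig,
    work_dir: str | Path,
) -> CheckpointRef:
    """Train the generalized model on the pre-training split.

    Each iteration draws one patient-fraction uniformly from the pre-training
    cohort, augments a patch and takes one optimizer step.  With
    ``cfg.pretrain_candidates > 1``, that run is repeated from fresh
    seed-derived initializations and data streams, and the candidate with
    the best mean whole-volume DSC on a small *pre-training-split*
    validation set wins (first fraction of up to three pre-training
    patients; test-split patients are never consulted) — single-patch
    optimization of a small net from a random initialization occasionally
    settles on the wrong structure, and because that structure is rarely
    sampled by the crop distribution, the failure is visible only at
    whole-volume scale, not in the training loss.  While the best
    validation DSC stays below ``cfg.pretrain_min_val_dsc`` extra restarts
    are spent, up to ``cfg.pretrain_max_candidates``.  The winner's
    parameters are loaded into ``model``; emits a stage="pretrain"
    checkpoint and a JSONL (iteration, loss) log.
    """
    work_dir = Path(work_dir)
    pretrain_ids = manifest.patient_ids("pretrain")
    if not pretrain_ids:
        raise ValueError("manifest has no pretrain-split patients")
    pairs = []
    for pid in pretrain_ids:
        for entry in manifest.entries_of(pid):
            pairs.append(_prepared_fraction(manifest, pid, entry.fraction_index, pre_cfg))

    val_ids = pretrain_ids[: min(3, len(pretrain_ids))]

    def validation_dsc(net: ReferenceNet) -> float:
        scores = []
        for pid in val_ids:
            fx = manifest.entries_of(pid)[0].fraction_index
            pred, ref = predict_mask(net, manifest, pid, fx, pre_cfg, overlap=0.25)
            scores.append(_dsc(ref, pred) if pred.any() else 0.0)
        return float(np.mean(scores))

    best: Optional[tuple[float, dict[str, np.ndarray], list[float]]] = None
    cand = 0
    while True:
        # Candidate 0 trains the model as passed in (fresh or resumed);
        # further candidates restart from seed-derived initializations.
        net = model if cand == 0 else type(model)(
            model.width, model.depth, seed=int(
                np.random.SeedSequence([cfg.seed, 7007, cand]).generate_state(1)[0]
                % (2**31 - 1)
            ),
        )
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11, cand]))
        optimizer = net.optimizer(cfg.lr, cfg.weight_decay)
        order = rng.integers(0, len(pairs), size=cfg.pretrain_iterations)
        losses = _train_steps(net, pairs, order, cfg, pre_cfg, rng, optimizer)
        multi = max(1, cfg.pretrain_candidates) > 1 or cfg.pretrain_min_val_dsc is not None
        score = validation_dsc(net) if multi else 1.0
        if best is None or score > best[0]:
            best = (score, {k: v.copy() for k, v in net.parameters().items()}, losses)
        cand += 1
        if cand < max(1, cfg.pretrain_candidates):
            continue
        # Bounded escalation while the best candidate looks unconverged.
        if (
            cfg.pretrain_min_val_dsc is not None
            and best[0] < cfg.pretrain_min_val_dsc
            and cand < cfg.pretrain_max_candidates
        ):
            continue
        break

    assert best is not None
    model.load_parameters(best[1])
    ref = CheckpointRef(
        path=work_dir / checkpoint_filename("pretrain", None, ()),
        stage="pretrain",
    )
    save_checkpoint(model.parameters(), ref)
    _write_log(ref.path, best[2])
    return ref


def _write_log(ckpt_path: Path, losses: Sequence[float]) -> None:
    with open(str(ckpt_path) + ".log.jsonl", "w") as fh:
        for i, loss in enumerate(losses):
            fh.write(json.dumps({"step": i, "loss": float(loss)}) + "\n")


# ---------------------------------------------------------------------------
# Stage 2: per-patient schedules


def _check_contiguous(fractions: Sequence[int]) -> list[int]:
    fr = sorted(int(f) for f in fractions)
    if fr != list(range(1, len(fr) + 1)):
        raise ValueError(
            f"fractions must be the contiguous set 1..n, got {fr}; "
            "a cohort with gaps cannot be scheduled"
        )
    return fr


def psn_adaptive_schedule(
    fractions: Sequence[int],
    pretrain_ckpt: CheckpointRef,
    patient_id: str = "",
) -> list[TrainTestStep]:
    """Cumulative fine-tuning: step k trains on fractions 1..k (restarting
    from the generalized checkpoint each step) and tests on k+1..n."""
    fr = _check_contiguous(fractions)
    n = len(fr)
    steps = []
    for k in range(1, n):
        steps.append(
            TrainTestStep(
                patient_id=patient_id,
                train_fractions=tuple(range(1, k + 1)),
                test_fractions=tuple(range(k + 1, n + 1)),
                init=pretrain_ckpt,
            )
        )
    return steps


def psn_sequence_schedule(
    fractions: Sequence[int],
    pretrain_ckpt: CheckpointRef,
    patient_id: str = "",
) -> list[TrainTestStep]:
    """Chained fine-tuning: step k trains on fraction k alone, initialized
    from the previous step's checkpoint (step 1 from the generalized model),
    and tests on fraction k+1.  Per-step training-set size is constant 1."""
    fr = _check_contiguous(fractions)
    n = len(fr)
    steps = []
    for k in range(1, n):
        steps.append(
            TrainTestStep(
                patient_id=patient_id,
                train_fractions=(k,),
                test_fractions=(k + 1,),
                init=pretrain_ckpt if k == 1 else None,  # None -> chained
            )
        )
    return steps


def _step_rng(cfg: TrainConfig, patient_id: str, step_ordinal: int) -> np.random.Generator:
    pid_hash = zlib.crc32(patient_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, pid_hash, step_ordinal]))


def fine_tune(
    step: TrainTestStep,
    manifest: CohortManifest,
    model: ReferenceNet,
    cfg: TrainConfig,
    pre_cfg: PreprocessConfig,
    work_dir: str | Path,
    stage: str = "adaptive",
) -> CheckpointRef:
    """Fine-tune ``model`` (already holding its initialization) on the step's
    training fractions for ``cfg.finetune_epochs`` epochs.

    One epoch = ``patches_per_volume_per_epoch`` seeded augmented patches per
    training fraction.  With zero epochs the emitted checkpoint equals the
    initialization.  Wall-time therefore scales with the training-set size:
    linearly growing across adaptive steps, constant across sequence steps
    (visible in the emitted logs).
    """
    work_dir = Path(work_dir)
    pairs = [
        _prepared_fraction(manifest, step.patient_id, fx, pre_cfg)
        for fx in step.train_fractions
    ]
    rng = _step_rng(cfg, step.patient_id, max(step.train_fractions))
    optimizer = model.optimizer(cfg.lr, cfg.weight_decay)
    losses: list[float] = []
    for _ in range(cfg.finetune_epochs):
        order = [i for i in range(len(pairs)) for _ in range(cfg.patches_per_volume_per_epoch)]
        losses.extend(_train_steps(model, pairs, order, cfg, pre_cfg, rng, optimizer))
    ref = CheckpointRef(
        path=work_dir / checkpoint_filename(stage, step.patient_id, step.train_fractions),
        stage=stage,
        patient_id=step.patient_id,
        trained_on=step.train_fractions,
    )
    save_checkpoint(model.parameters(), ref)
    _write_log(ref.path, losses)
    step.out = ref
    return ref


def run_schedule(
    steps: list[TrainTestStep],
    manifest: CohortManifest,
    model: ReferenceNet,
    cfg: TrainConfig,
    pre_cfg: PreprocessConfig,
    work_dir: str | Path,
    stage: str,
) -> list[TrainTestStep]:
    """Execute a schedule in order, chaining checkpoints where a step's
    ``init`` is None (the sequence strategy)."""
    prev_out: Optional[CheckpointRef] = None
    for step in steps:
        init = step.init if step.init is not None else prev_out
        if init is None:
            raise ValueError("first step of a schedule must name its initialization")
        params, _ = load_checkpoint(init.path)
        model.load_parameters(params)
        fine_tune(step, manifest, model, cfg, pre_cfg, work_dir, stage=stage)
        prev_out = step.out
    return steps


# ---------------------------------------------------------------------------
# Evaluation


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Postprocessing: keep only the largest 26-connected foreground island.

    The target is a single connected structure, so any detached islands are
    false positives of patch-wise inference.
    """
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    if n <= 1:
        return mask.astype(np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (labels == keep).astype(np.uint8)


def predict_mask(
    model: ReferenceNet,
    manifest: CohortManifest,
    patient_id: str,
    fraction: int,
    pre_cfg: PreprocessConfig,
    overlap: float = 0.5,
    postprocess: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window prediction for one fraction; returns (prediction,
    reference) masks on the evaluation grid.  No augmentation at test time;
    postprocessing keeps the largest connected component."""
    img, msk = _prepared_fraction(manifest, patient_id, fraction, pre_cfg)
    x = normalize_intensity(img, pre_cfg.hu_window)
    pred = sliding_window_predict(model, x, pre_cfg.crop_size, overlap=overlap)
    if postprocess and pred.any():
        pred = largest_component(pred)
    return pred, msk


def _pair_metrics(
    reference: np.ndarray, pred: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[float, float, float]:
    """DSC/HD95/MSD with a defined convention for empty predictions: zero
    overlap and the grid diagonal as a conservative finite distance."""
    if not pred.any():
        diag = float(np.linalg.norm(np.asarray(reference.shape) * np.asarray(spacing)))
        return 0.0, diag, diag
    d = surface_distances(reference, pred, spacing)
    return _dsc(reference, pred), float(np.percentile(d, 95)), float(np.mean(d))


def evaluate_schedule(
    steps: list[TrainTestStep],
    manifest: CohortManifest,
    model: ReferenceNet,
    pre_cfg: PreprocessConfig,
    method: str,
) -> pd.DataFrame:
    """Geometric metrics of every completed step on its test fractions.

    Tidy output mirroring the paper-style layout: one row per (patient,
    training extent, evaluated fraction) with columns method, dsc, hd95_mm,
    msd_mm.
    """
    rows = []
    spacing = tuple(pre_cfg.target_spacing_mm)
    for step in steps:
        if step.out is None:
            raise ValueError(f"step {step.train_fractions} has no trained checkpoint")
        params, _ = load_checkpoint(step.out.path)
        model.load_parameters(params)
        for fx in step.test_fractions:
            pred, ref = predict_mask(model, manifest, step.patient_id, fx, pre_cfg)
            d, h, m = _pair_metrics(ref, pred, spacing)
            rows.append(
                {
                    "patient": step.patient_id,
                    "method": method,
                    "trained_through": max(step.train_fractions),
                    "test_fraction": fx,
                    "dsc": d,
                    "hd95_mm": h,
                    "msd_mm": m,
                }
            )
    return pd.DataFrame(rows)
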