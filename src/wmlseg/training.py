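"""Optimization loop (batch size 1, ADAM), loss-ranked training-set curation,
and the cross-modality training driver that supervises a high-res net from
thick-slice targets through the sparse sampling map.

The curation workflow operationalizes a two-step scheme: first train a
thick-slice-space net to mimic the provided (possibly flawed) targets and
rank samples by their per-sample loss — networks learn the main trends of a
dataset before its deviations, so badly-labelled samples surface at the top —
then retrain on a corrected dataset in which fixed samples are visited
``oversample_factor`` (default 10) times per epoch, each visit drawing fresh
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .augment import AugmentParams, random_affine
from .grids import RigidTransform, Volume, build_sampling_map, resample
from .losses import RIBBON_WEIGHT
from .nets import Model, build_flair_net, build_t1_wmh_net

__all__ = [
    "TrainConfig",
    "CurationReport",
    "FlairSample",
    "T1Sample",
    "train",
    "rank_by_loss",
    "build_curated_dataset",
    "two_step_flair_workflow",
    "train_t1_from_flair",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    warmup_steps: int = 0  # linear lr ramp over the first N visits
    max_epochs: int = 10
    stop_patience: int = 0  # 0 disables the slower-convergence stop rule
    stop_slope: float = 1e-3  # relative moving-average decrease per window
    seed: int = 0
    width_scale: float = 0.125
    ribbon_weight: float = RIBBON_WEIGHT
    normalize_loss: bool = False  # mean (per-voxel) instead of summed terms
    positive_weight: float = 1.0  # up-weight positive lesion targets
    oversample_factor: int = 10
    augment: AugmentParams | None = None
    shuffle: bool = True

    def __post_init__(self):
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")


@dataclass
class CurationReport:
    sample_ids: list
    losses: np.ndarray
    ranks: np.ndarray  # 1 = largest loss; a permutation of 1..N
    regional_volumes: list | None = None
    flags: list | None = None  # corrected | dropped | kept per sample

    def top(self, k: int) -> list:
        order = np.argsort(self.ranks)
        return [self.sample_ids[i] for i in order[:k]]


@dataclass
class FlairSample:
    id: str
    image: Volume
    target: Volume  # binary lesion mask on the thick-slice grid


@dataclass
class T1Sample:
    id: str
    t1: Volume
    flair_wmh: Volume  # target on its native thick-slice grid
    ribbon: Volume  # dense auxiliary target on the T1 grid
    rigid: RigidTransform  # FLAIR -> T1 world transform


def train(model: Model, dataset, loss_fn, cfg: TrainConfig):
    """Single-sample iteration with fresh per-visit randomness.

    ``loss_fn(model, sample, rng)`` must run the forward pass, return
    ``(loss, grad_wrt_output)``, and treat ``rng=None`` as "no augmentation".
    Stops at ``max_epochs`` or when the moving-average loss over the last
    ``stop_patience`` epochs has decreased by less than ``stop_slope``
    relative to the preceding window. Returns ``(model, loss_history)``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer(lr=cfg.learning_rate)
    history = []
    step = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(dataset)) if cfg.shuffle else np.arange(len(dataset))
        epoch_losses = []
        for i in order:
            step += 1
            if cfg.warmup_steps:
                opt.lr = cfg.learning_rate * min(1.0, step / cfg.warmup_steps)
            opt.zero_grad()
            loss, gout = loss_fn(model, dataset[i], rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at sample index {i}")
            model.backward(np.asarray(gout, dtype=np.float32))
            opt.step()
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
        p = cfg.stop_patience
        if p > 0 and len(history) >= 2 * p:
            recent = np.mean(history[-p:])
            before = np.mean(history[-2 * p : -p])
            if before > 0 and (before - recent) / before < cfg.stop_slope:
                break
    return model, history


def rank_by_loss(model: Model, dataset, loss_fn, sample_ids=None,
                 regional_volumes=None) -> CurationReport:
    """Per-sample evaluation-mode loss (no augmentation), ranked descending.

    Ties keep dataset order (stable sort)."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    losses = []
    for sample in dataset:
        loss, _ = loss_fn(model, sample, None)
        losses.append(loss)
    losses = np.asarray(losses, dtype=float)
    order = np.argsort(-losses, kind="stable")
    ranks = np.empty(len(losses), dtype=int)
    ranks[order] = np.arange(1, len(losses) + 1)
    if sample_ids is None:
        sample_ids = [getattr(s, "id", str(i)) for i, s in enumerate(dataset)]
    return CurationReport(
        sample_ids=list(sample_ids),
        losses=losses,
        ranks=ranks,
        regional_volumes=regional_volumes,
        flags=["kept"] * len(losses),
    )


def build_curated_dataset(dataset, corrections: dict, drops: set,
                          oversample_factor: int):
    """Drop, correct and oversample: corrected samples get their target
    replaced and appear ``oversample_factor`` times in each epoch."""
    ids = {s.id for s in dataset}
    unknown = (set(corrections) | set(drops)) - ids
    if unknown:
        raise KeyError(f"corrections/drops reference unknown sample ids: {sorted(unknown)}")
    out = []
    for s in dataset:
        if s.id in drops:
            continue
        if s.id in corrections:
            fixed = replace(s, target=corrections[s.id])
            out.extend([fixed] * int(oversample_factor))
        else:
            out.append(s)
    return out


def _flair_loss_fn(cfg: TrainConfig):
    """Dense squared-error mimic loss on output channel 0 of the FLAIR net,
    with optional axial-only rigid augmentation of image and target."""

    def loss_fn(model, sample: FlairSample, rng):
        image, target = sample.image, sample.target
        if rng is not None and cfg.augment is not None:
            t = random_affine(cfg.augment, seed=int(rng.integers(2**31)))
            image = resample(image, image.grid, transform=t, mode="trilinear")
            target = resample(target, target.grid, transform=t, mode="nearest")
        out = model.forward(image.data)
        diff = out[0].astype(np.float64) - target.data
        loss = float(np.sum(diff * diff))
        gout = np.zeros_like(out)
        gout[0] = 2.0 * diff
        return loss, gout

    return loss_fn


def two_step_flair_workflow(dataset, cfg: TrainConfig, corrections=None, drops=None):
    """Mimic-train, rank, correct, retrain with oversampling, then emit
    model-generated reference masks for the whole dataset.

    Returns ``(flair_model, reference_masks, report)`` where
    ``reference_masks`` maps sample id to a probability Volume on the
    sample's thick-slice grid.
    """
    corrections = dict(corrections or {})
    drops = set(drops or ())
    loss_fn = _flair_loss_fn(cfg)
    model = build_flair_net(width_scale=cfg.width_scale, seed=cfg.seed)
    model, _ = train(model, list(dataset), loss_fn, cfg)
    report = rank_by_loss(model, list(dataset), loss_fn)
    if corrections or drops:
        curated = build_curated_dataset(dataset, corrections, drops,
                                        cfg.oversample_factor)
        model, _ = train(model, curated, loss_fn, replace(cfg, seed=cfg.seed + 1))
        flag = {s.id: "kept" for s in dataset}
        flag.update({i: "corrected" for i in corrections})
        flag.update({i: "dropped" for i in drops})
        report.flags = [flag[i] for i in report.sample_ids]
    reference_masks = {
        s.id: Volume(model.forward(s.image.data)[0].astype(np.float64), s.image.grid)
        for s in dataset
    }
    return model, reference_masks, report


def train_t1_from_flair(t1_dataset, cfg: TrainConfig, loss: str = "sparse",
                        model: Model | None = None, lesion_weight: float = 1.0):
    """Train the high-res lesion net from thick-slice targets.

    Each visit draws a fresh augmentation transform, warps the input volume
    and the dense ribbon target through it, and rebuilds the sampling map
    with the augmentation composed in — the thick-slice target itself is
    never interpolated. ``loss='dense'`` switches to the trilinear
    interpolating baseline. A pre-built (e.g. warm-started) ``model`` may be
    supplied; ``lesion_weight=0`` trains the auxiliary ribbon head only.
    Returns ``(model, loss_history)``.
    """
    if loss not in ("sparse", "dense"):
        raise ValueError(f"unknown loss {loss!r}")

    def loss_fn(model, sample: T1Sample, rng):
        t1, ribbon = sample.t1, sample.ribbon
        aug = None
        if rng is not None and cfg.augment is not None:
            aug = random_affine(cfg.augment, seed=int(rng.integers(2**31)))
            t1 = resample(t1, t1.grid, transform=aug, mode="trilinear")
            ribbon = resample(ribbon, ribbon.grid, transform=aug, mode="nearest")
        out = model.forward(t1.data)
        out1 = Volume(out[0].astype(np.float64), t1.grid)
        out2 = Volume(out[1].astype(np.float64), t1.grid)
        from .losses import (
            dense_interpolating_loss,
            dense_interpolating_loss_grad as dense_grad,
            ribbon_loss,
            ribbon_loss_grad,
            sparse_lesion_loss,
            sparse_lesion_loss_grad,
        )

        pw = cfg.positive_weight
        if loss == "sparse":
            smap = build_sampling_map(sample.flair_wmh.grid, t1.grid, sample.rigid,
                                      aug=aug)
            if pw == 1.0:
                lesion_term = sparse_lesion_loss(out1, sample.flair_wmh, smap)
                g1 = sparse_lesion_loss_grad(out1, sample.flair_wmh, smap)
            else:
                fidx = tuple(smap.flair_indices.T)
                tidx = tuple(smap.t1_indices.T)
                tvals = sample.flair_wmh.data[fidx]
                w = np.where(tvals > 0.5, pw, 1.0)
                diff = out1.data[tidx] - tvals
                lesion_term = float(np.sum(w * diff**2))
                g1 = np.zeros(out1.grid.shape)
                np.add.at(g1, tidx, 2.0 * w * diff)
            n_lesion = max(smap.n_pairs, 1)
        else:
            combined = aug.compose(sample.rigid) if aug is not None else sample.rigid
            if pw == 1.0:
                lesion_term = dense_interpolating_loss(out1, sample.flair_wmh, combined)
                g1 = dense_grad(out1, sample.flair_wmh, combined)
            else:
                target = resample(sample.flair_wmh, out1.grid, combined, "trilinear")
                ones = Volume(np.ones(sample.flair_wmh.grid.shape),
                              sample.flair_wmh.grid)
                fov = resample(ones, out1.grid, combined, "trilinear").data > 0
                w = np.where(target.data > 0.5, pw, 1.0) * fov
                diff = out1.data - target.data
                lesion_term = float(np.sum(w * diff**2))
                g1 = 2.0 * w * diff
            n_lesion = out1.grid.n_voxels
        rb = ribbon_loss(out2, ribbon)
        g2 = ribbon_loss_grad(out2, ribbon)
        lw, rw = lesion_weight, cfg.ribbon_weight
        if cfg.normalize_loss:
            # per-voxel means keep the lesion/ribbon balance comparable
            # across supervision schemes with very different voxel counts
            lw = lw / n_lesion
            rw = rw / out2.grid.n_voxels
        total = lw * lesion_term + rw * rb
        return total, np.stack([lw * g1, rw * g2]).astype(np.float32)

    if model is None:
        model = build_t1_wmh_net(width_scale=cfg.width_scale, seed=cfg.seed)
    return train(model, list(t1_dataset), loss_fn, cfg)
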