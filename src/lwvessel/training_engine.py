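"""Training protocol: joint cross-entropy on both W-Net subnets, Adam with a
cyclically cosine-annealed learning rate, 50-epoch cycles sized to reach a
target number of gradient steps, batch size 4, standard augmentation, and
best-model selection by pooled validation AUC at cycle ends.

"Iterations" are gradient steps; the number of cycles is
ceil(target_iterations / (cycle_epochs * steps_per_epoch)), so small training
sets run more cycles.  Within a cycle the learning rate decays from
``lr_max`` to ``lr_min`` following a cosine law and restarts at ``lr_max`` at
the next cycle.  Loss pixels outside the FOV are included by default (FOV
exclusion is an evaluation-protocol rule); set ``loss_in_fov_only`` to restrict.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from . import nn
from .cli_io import Sample
from .evaluation import _auc_flat
from .model_zoo import ArchSpec, build_model


@dataclass(frozen=True)
class AugmentConfig:
    """Standard augmentation: geometric transforms hit image, label and FOV
    identically; photometric jitter hits the image only.  All ranges are
    symmetric around the identity and individually switchable."""

    hflip: bool = True
    vflip: bool = True
    rotate_deg: float = 45.0
    scale_jitter: float = 0.10
    brightness: float = 0.20
    contrast: float = 0.20
    gamma: float = 0.20

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(False, False, 0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def flips_only(cls) -> "AugmentConfig":
        return cls(True, True, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TrainConfig:
    lr_max: float = 1e-2
    lr_min: float = 1e-8
    cycle_epochs: int = 50
    target_iterations: int = 4000
    batch_size: int = 4
    train_resize: tuple[int, int] | None = None
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    loss_in_fov_only: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (self.lr_max > self.lr_min > 0):
            raise ValueError("need lr_max > lr_min > 0")
        if self.batch_size < 1 or self.target_iterations < 1 or self.cycle_epochs < 1:
            raise ValueError("batch_size, cycle_epochs, target_iterations must be >= 1")


@dataclass
class CheckpointBundle:
    """Best weights plus the per-cycle validation-AUC trace."""

    model: object
    val_auc_history: list[float]
    best_cycle: int
    loss_history: list[float]

    @property
    def best_val_auc(self) -> float:
        return self.val_auc_history[self.best_cycle]


def plan_cycles(n_train: int, cfg: TrainConfig) -> tuple[int, int, int]:
    """(steps_per_epoch, cycle_steps, n_cycles): cycles are sized so the total
    number of gradient steps reaches ``cfg.target_iterations``."""
    if n_train < 1:
        raise ValueError("empty training set")
    steps_per_epoch = math.ceil(n_train / cfg.batch_size)
    cycle_steps = cfg.cycle_epochs * steps_per_epoch
    n_cycles = math.ceil(cfg.target_iterations / cycle_steps)
    return steps_per_epoch, cycle_steps, n_cycles


def cosine_lr(step: int, cycle_steps: int, lr_max: float = 1e-2,
              lr_min: float = 1e-8) -> float:
    """lambda(step) = lr_min + (lr_max - lr_min) (1 + cos(pi step / cycle_steps)) / 2."""
    if cycle_steps <= 0:
        raise ValueError("cycle_steps must be positive")
    if not (0 <= step <= cycle_steps):
        raise ValueError(f"step {step} outside [0, {cycle_steps}]")
    return lr_min + (lr_max - lr_min) * (1.0 + math.cos(math.pi * step / cycle_steps)) / 2.0


def wnet_loss(out1, out2, target, fov=None):
    """Joint loss: sum (unit weights) of the two subnets' mean binary
    cross-entropies against the (possibly soft) target."""
    t1 = out1 if isinstance(out1, nn.Tensor) else nn.Tensor(out1)
    t2 = out2 if isinstance(out2, nn.Tensor) else nn.Tensor(out2)
    y = np.asarray(target, dtype=np.float32)
    w = None if fov is None else np.asarray(fov, dtype=np.float32)
    return nn.add(nn.bce_mean(t1, y, weight=w), nn.bce_mean(t2, y, weight=w))


# ------------------------------------------------------------- augmentation

def augment_arrays(image, label, fov, rng: np.random.Generator,
                   cfg: AugmentConfig):
    """Augment float arrays: image (H,W,3) in [0,1], label (H,W) in [0,1]
    (may be soft), fov (H,W) binary."""
    img, lab, f = image, label, fov
    if cfg.hflip and rng.random() < 0.5:
        img, lab, f = img[:, ::-1], lab[:, ::-1], f[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        img, lab, f = img[::-1], lab[::-1], f[::-1]
    if cfg.rotate_deg > 0 or cfg.scale_jitter > 0:
        angle = np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
        scale = 1.0 + rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)
        h, w = img.shape[:2]
        center = np.array([w / 2.0, h / 2.0])
        # inverse (output -> input) similarity around the image center
        inv = (AffineTransform(translation=-center)
               + AffineTransform(rotation=-angle, scale=1.0 / scale)
               + AffineTransform(translation=center))
        binary_label = np.isin(np.unique(lab), (0.0, 1.0)).all()
        img = warp(img, inv, order=1, mode="constant", cval=0.0, preserve_range=True)
        lab = warp(lab, inv, order=0 if binary_label else 1,
                   mode="constant", cval=0.0, preserve_range=True)
        f = warp(f, inv, order=0, mode="constant", cval=0.0, preserve_range=True)
    img = np.asarray(img, dtype=np.float32)
    if cfg.brightness > 0:
        img = img + rng.uniform(-cfg.brightness, cfg.brightness)
    if cfg.contrast > 0:
        c = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        img = (img - 0.5) * c + 0.5
    img = np.clip(img, 0.0, 1.0)
    if cfg.gamma > 0:
        img = img ** (1.0 + rng.uniform(-cfg.gamma, cfg.gamma))
    return (np.ascontiguousarray(img),
            np.ascontiguousarray(np.asarray(lab, dtype=np.float32)),
            np.ascontiguousarray(np.asarray(f, dtype=np.float32)))


def augment(sample: Sample, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> Sample:
    """Augment a :class:`Sample`, preserving image/label/FOV alignment."""
    cfg = cfg or AugmentConfig()
    img, lab, f = augment_arrays(sample.image_float(),
                                 sample.label.astype(np.float32),
                                 sample.fov.astype(np.float32), rng, cfg)
    return Sample(image=np.floor(img * 255.0 + 0.5).astype(np.uint8),
                  label=(lab >= 0.5).astype(np.uint8),
                  fov=(f >= 0.5).astype(np.uint8),
                  native_size=sample.native_size)


# ------------------------------------------------------------ training loop

def _prepare_items(samples: list[Sample], size: tuple[int, int] | None,
                   divisor: int):
    items = []
    for s in samples:
        img = s.image_float()
        target = (s.pseudolabel if s.pseudolabel is not None
                  else s.label).astype(np.float32)
        f = s.fov.astype(np.float32)
        if size is not None and img.shape[:2] != tuple(size):
            soft = s.pseudolabel is not None
            img = resize(img, size + (3,), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True).astype(np.float32)
            target = resize(target, size, order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
            if not soft:
                target = (target >= 0.5).astype(np.float32)
            f = (resize(f, size, order=0, mode="edge",
                        preserve_range=True) >= 0.5).astype(np.float32)
        h, w = img.shape[:2]
        if h % divisor or w % divisor:
            raise ValueError(
                f"training size {h}x{w} not divisible by 2^(k-1)={divisor}; "
                "set train_resize accordingly")
        items.append({"image": img, "target": np.asarray(target, np.float32),
                      "fov": f})
    return items


def _val_auc(model, val_items) -> float:
    model.eval()
    probs, labels = [], []
    with nn.no_grad():
        for it in val_items:
            out = model(nn.Tensor(it["image"][None]))
            if isinstance(out, tuple):
                out = out[-1]
            mask = it["fov"] >= 0.5
            probs.append(out.data[0, ..., 0][mask])
            labels.append((it["target"][mask] >= 0.5).astype(np.int8))
    model.train(True)
    return _auc_flat(np.concatenate(probs).astype(np.float64),
                     np.concatenate(labels))


def run_training(train_samples: list[Sample], val_samples: list[Sample],
                 spec: ArchSpec | None = None, cfg: TrainConfig | None = None,
                 kind: str = "wnet", model=None) -> CheckpointBundle:
    """Cyclical training with per-cycle validation-AUC model selection.

    Either ``spec`` (a model is built, seeded from ``cfg.seed``) or an
    already-built ``model`` must be given.  Fully reproducible given the seed.
    """
    cfg = cfg or TrainConfig()
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    if model is None:
        if spec is None:
            raise ValueError("provide spec or model")
        model = build_model(spec, kind, seed=cfg.seed)
    is_wnet = model.kind == "wnet"
    divisor = model.spec.divisor

    items = _prepare_items(train_samples, cfg.train_resize, divisor)
    val_items = _prepare_items(val_samples, cfg.train_resize, divisor)
    rng = np.random.default_rng(cfg.seed)

    steps_per_epoch, cycle_steps, n_cycles = plan_cycles(len(items), cfg)

    opt = nn.Adam(model.parameters(), lr=cfg.lr_max)
    best_state, best_auc, best_cycle = None, -np.inf, -1
    auc_history: list[float] = []
    loss_history: list[float] = []
    model.train(True)

    for cycle in range(n_cycles):
        step_in_cycle = 0
        for _ in range(cfg.cycle_epochs):
            order = rng.permutation(len(items))
            for start in range(0, len(items), cfg.batch_size):
                batch_idx = order[start:start + cfg.batch_size]
                imgs, targets, fovs = [], [], []
                for j in batch_idx:
                    it = items[j]
                    img, lab, f = augment_arrays(it["image"], it["target"],
                                                 it["fov"], rng, cfg.augment)
                    imgs.append(img)
                    targets.append(lab[..., None])
                    fovs.append(f[..., None])
                xb = np.stack(imgs)
                yb = np.stack(targets)
                wb = np.stack(fovs) if cfg.loss_in_fov_only else None
                opt.lr = cosine_lr(step_in_cycle, cycle_steps,
                                   cfg.lr_max, cfg.lr_min)
                opt.zero_grad()
                out = model(nn.Tensor(xb))
                if is_wnet:
                    loss = wnet_loss(out[0], out[1], yb, fov=wb)
                else:
                    loss = nn.bce_mean(out, yb, weight=wb)
                loss.backward()
                opt.step()
                loss_history.append(loss.item())
                step_in_cycle += 1
        auc = _val_auc(model, val_items)
        auc_history.append(auc)
        if auc > best_auc:  # first cycle achieving the max wins ties
            best_auc, best_cycle = auc, cycle
            best_state = copy.deepcopy(model.state_dict())

    model.load_state_dict(best_state)
    model.eval()
    return CheckpointBundle(model=model, val_auc_history=auc_history,
                            best_cycle=best_cycle, loss_history=loss_history)
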