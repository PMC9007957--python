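"""Pseudo-label self-training: the single-round domain-adaptation baseline.

A model trained on a labeled source dataset generates *soft* (unthresholded)
probability maps on the unlabeled target images; source labels and target
pseudo-labels are merged into one pool; the model is fine-tuned on that pool
for 10 epochs at a constant learning rate reduced 100-fold from the training
peak; the best fine-tuned model is chosen by pooled AUC on the merged pool.
Keeping the pseudo-labels soft exposes the model to its own uncertainty on the
target domain instead of committing to hard decisions.

AUC needs binary references, so pseudo-labels are binarized at 0.5 *for
monitoring only* — the fine-tuning loss always uses the soft targets.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np

from . import nn
from .cli_io import Sample
from .evaluation import _auc_flat
from .inference import predict_tta
from .training_engine import TrainConfig, _prepare_items, augment_arrays, wnet_loss

ADAPT_EPOCHS = 10
LR_REDUCTION = 100.0


def make_pseudolabels(model, target_samples: list[Sample],
                      train_resize: tuple[int, int] | None = None,
                      tta: bool = True) -> list[np.ndarray]:
    """Soft probability maps for target images at the training resolution."""
    from skimage.transform import resize as sk_resize

    out = []
    for s in target_samples:
        img = s.image_float()
        if train_resize is not None and img.shape[:2] != tuple(train_resize):
            img = sk_resize(img, tuple(train_resize) + (3,), order=1,
                            mode="edge", anti_aliasing=False,
                            preserve_range=True).astype(np.float32)
        prob = predict_tta(model, img, tta=tta)
        out.append(np.clip(prob, 0.0, 1.0).astype(np.float32))
    return out


def attach_pseudolabels(target_samples: list[Sample],
                        pseudolabels: list[np.ndarray]) -> list[Sample]:
    """New Samples carrying the soft maps as training targets (inputs untouched)."""
    out = []
    for s, pl in zip(target_samples, pseudolabels):
        out.append(Sample(image=s.image.copy(), label=s.label.copy(),
                          fov=s.fov.copy(), native_size=s.native_size,
                          pseudolabel=np.asarray(pl, dtype=np.float32)))
    return out


def _merged_pool_auc(model, items) -> float:
    """Pooled AUC over the merged pool; pseudo-label targets binarized at 0.5."""
    model.eval()
    probs, labels = [], []
    with nn.no_grad():
        for it in items:
            out = model(nn.Tensor(it["image"][None]))
            if isinstance(out, tuple):
                out = out[-1]
            mask = it["fov"] >= 0.5
            probs.append(out.data[0, ..., 0][mask].astype(np.float64))
            labels.append((it["target"][mask] >= 0.5).astype(np.int8))
    model.train(True)
    return _auc_flat(np.concatenate(probs), np.concatenate(labels))


def adapt(model, source_samples: list[Sample],
          target_samples: list[Sample], cfg: TrainConfig | None = None):
    """Fine-tune on source labels + target pseudo-labels; returns a new model.

    ``target_samples`` must carry ``pseudolabel`` maps (see
    :func:`attach_pseudolabels`).  The input model is never modified; with an
    empty target set it is returned unchanged (with a warning).
    """
    cfg = cfg or TrainConfig()
    if not target_samples:
        warnings.warn("empty target set: returning the source model unchanged")
        return model
    for s in target_samples:
        if s.pseudolabel is None:
            raise ValueError("target samples must carry pseudolabels; "
                             "run make_pseudolabels/attach_pseudolabels first")

    adapted = copy.deepcopy(model)
    adapted.train(True)
    divisor = adapted.spec.divisor
    items = (_prepare_items(source_samples, cfg.train_resize, divisor)
             + _prepare_items(target_samples, cfg.train_resize, divisor))
    rng = np.random.default_rng(cfg.seed)
    lr = cfg.lr_max / LR_REDUCTION
    opt = nn.Adam(adapted.parameters(), lr=lr)
    is_wnet = adapted.kind == "wnet"

    best_state, best_auc = copy.deepcopy(adapted.state_dict()), -np.inf
    for _ in range(ADAPT_EPOCHS):
        order = rng.permutation(len(items))  # source and target mixed uniformly
        for start in range(0, len(items), cfg.batch_size):
            imgs, targets, fovs = [], [], []
            for j in order[start:start + cfg.batch_size]:
                it = items[j]
                img, lab, f = augment_arrays(it["image"], it["target"],
                                             it["fov"], rng, cfg.augment)
                imgs.append(img)
                targets.append(np.clip(lab, 1e-6, 1.0 - 1e-6)[..., None])
                fovs.append(f[..., None])
            xb, yb = np.stack(imgs), np.stack(targets)
            wb = np.stack(fovs) if cfg.loss_in_fov_only else None
            opt.zero_grad()
            out = adapted(nn.Tensor(xb))
            if is_wnet:
                loss = wnet_loss(out[0], out[1], yb, fov=wb)
            else:
                loss = nn.bce_mean(out, yb, weight=wb)
            loss.backward()
            opt.step()
        auc = _merged_pool_auc(adapted, items)
        if auc > best_auc:
            best_auc = auc
            best_state = copy.deepcopy(adapted.state_dict())
    adapted.load_state_dict(best_state)
    adapted.eval()
    return adapted
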