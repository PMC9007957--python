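"""Probability-map inference: flip test-time augmentation and native-resolution
restoration.

TTA averages predictions over the 4-element flip group {identity, horizontal,
vertical, both}; because the set is a closed group, TTA output is exactly
flip-equivariant.  A 3-transform variant (without the double flip) is available
for compatibility with readings of "horizontal and vertical flips" as two extra
passes.  Images whose sides are not divisible by 2^(k-1) are reflect-padded to
the next multiple and the output is cropped back, avoiding any resampling of
the input.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from . import nn

#: flip sets as (flip_horizontal, flip_vertical) pairs
FLIP_SETS = {
    "group4": ((False, False), (True, False), (False, True), (True, True)),
    "three": ((False, False), (True, False), (False, True)),
    "none": ((False, False),),
}


def _as_chw_last(image: np.ndarray) -> np.ndarray:
    """Accept (H, W), (H, W, C); return float32 (H, W, C)."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D image grid, got shape {arr.shape}")
    return arr


def _flip(arr: np.ndarray, fh: bool, fv: bool) -> np.ndarray:
    if fh:
        arr = arr[:, ::-1]
    if fv:
        arr = arr[::-1, :]
    return arr


def _forward_prob(model, image_hwc: np.ndarray) -> np.ndarray:
    """Single forward pass -> (H, W) or (H, W, classes) probability grid."""
    x = nn.Tensor(image_hwc[None])
    with nn.no_grad():
        out = model(x)
    if isinstance(out, tuple):       # W-Net exposes both subnets; final is last
        out = out[-1]
    prob = out.data[0]
    return prob[..., 0] if prob.shape[-1] == 1 else prob


def predict_proba(model, image: np.ndarray) -> np.ndarray:
    """Plain (no TTA) prediction with reflect pad-and-crop to a legal size."""
    img = _as_chw_last(image)
    h, w = img.shape[:2]
    d = model.spec.divisor
    ph, pw = (-h) % d, (-w) % d
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    prob = _forward_prob(model, img)
    return np.ascontiguousarray(prob[:h, :w])


def predict_tta(model, image: np.ndarray, flips: str = "group4",
                tta: bool = True) -> np.ndarray:
    """Mean of un-flipped predictions over the flip set; values in [0, 1]."""
    if not tta:
        return predict_proba(model, image)
    img = _as_chw_last(image)
    acc = None
    flip_set = FLIP_SETS[flips]
    for fh, fv in flip_set:
        p = predict_proba(model, _flip(img, fh, fv))
        p = _flip(p, fh, fv)
        acc = p.copy() if acc is None else acc + p
    return acc / len(flip_set)


def restore_native(prob: np.ndarray, native_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of a probability map to native resolution.

    Resampling happens on probabilities — thresholding only afterwards — and
    the result is clamped to [0, 1].
    """
    nh, nw = int(native_size[0]), int(native_size[1])
    if nh <= 0 or nw <= 0:
        raise ValueError(f"non-positive native size {native_size}")
    p = np.asarray(prob, dtype=np.float64)
    if p.shape[:2] == (nh, nw):
        return p.astype(np.float32)
    out = resize(p, (nh, nw) + p.shape[2:], order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)
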