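"""Synthetic fundus-style samples: a branching dark vascular tree inside a
bright circular field of view on a textured, illumination-graded background.

The generator emulates the structure of fundus vessel-segmentation datasets —
an RGB photograph, a binary vessel label and a binary FOV disc — with knobs for
the axes along which real datasets differ (illumination gradient, optic-disc vs
macula centering, resolution).  Presets named ``source`` and ``target_*`` are
identical except for the single documented field, so cross-"dataset"
experiments isolate one domain-shift axis at a time.

Vessel geometry is a recursive random walk: stems leave the optic-disc locus
with fanned headings, wander with Gaussian heading noise, taper slowly, and
bifurcate with a fixed per-step probability into two children of decayed
caliber; growth stops below 1 px caliber or outside the FOV.  The per-sample
tree depends only on (seed, index) and the tree parameters, so presets that
differ in appearance alone share byte-identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cli_io import Sample


@dataclass(frozen=True)
class SynthParams:
    # geometry
    size: tuple[int, int] = (128, 128)
    fov_radius_frac: float = 0.95        # of half the smaller image side
    centering: str = "macula"            # "macula" (OD near edge) or "od" (OD centered)
    # vessel tree
    n_stems: int = 5
    branch_prob: float = 0.10            # bifurcation probability per step
    angle_range: tuple[float, float] = (30.0, 70.0)   # bifurcation angle, degrees
    init_caliber: float = 1.8            # stroke radius at the root, px
    caliber_decay: float = 0.80          # per-bifurcation radius factor
    step_len: float = 2.5                # px per step
    tortuosity: float = 0.18             # heading noise sd, radians/step
    taper: float = 0.995                 # per-step radius factor
    max_steps: int = 120                 # safety cap per branch
    # appearance
    base_color: tuple[float, float, float] = (0.72, 0.38, 0.18)  # fundus orange
    illumination: float = 0.25           # radial darkening strength at the FOV rim
    texture: float = 0.04                # low-frequency background texture amplitude
    noise_sd: float = 0.02               # additive pixel noise sd
    vessel_contrast: float = 0.55        # relative darkening under a vessel
    central_reflex: bool = False

    def __post_init__(self):
        if not (0.0 < self.caliber_decay <= 1.0):
            raise ValueError("caliber decay must be in (0, 1]")
        if not (0.0 < self.fov_radius_frac <= 1.0):
            raise ValueError("FOV radius fraction must be in (0, 1]")
        if self.centering not in ("macula", "od"):
            raise ValueError(f"unknown centering {self.centering!r}")


#: presets differ from ``source`` in exactly one field
PRESETS: dict[str, dict] = {
    "source": {},
    "target_illumination": {"illumination": 0.60},
    "target_od_centered": {"centering": "od"},
    "target_lowres": {"size": (64, 64)},
}


def preset_params(preset: str) -> SynthParams:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return SynthParams(**PRESETS[preset])


def _fov_geometry(params: SynthParams):
    h, w = params.size
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    radius = params.fov_radius_frac * (min(h, w) / 2.0)
    return center, radius


def _od_locus(params: SynthParams):
    """Root locus of the vessel tree (the optic disc)."""
    center, radius = _fov_geometry(params)
    if params.centering == "od":
        return center
    # macula-centered photographs show the OD displaced toward one side
    return center + np.array([0.0, -0.72 * radius])


def sample_vessel_tree(params: SynthParams, rng: np.random.Generator):
    """Random branching walk; returns segments (r0, c0, r1, c1, caliber)."""
    center, radius = _fov_geometry(params)
    od = _od_locus(params)
    segments: list[tuple[float, float, float, float, float]] = []
    if params.n_stems <= 0:
        return segments
    lo, hi = np.deg2rad(params.angle_range[0]), np.deg2rad(params.angle_range[1])
    # fan the stems out of the OD, biased toward the FOV center
    to_center = np.arctan2(center[0] - od[0], center[1] - od[1])
    headings = to_center + np.linspace(-1.1, 1.1, params.n_stems) \
        + rng.normal(0, 0.1, params.n_stems)
    stack = [(od.copy(), float(th), float(params.init_caliber)) for th in headings]
    while stack:
        pos, heading, caliber = stack.pop()
        for _ in range(params.max_steps):
            if caliber < 1.0:
                break
            heading += rng.normal(0.0, params.tortuosity)
            new = pos + params.step_len * np.array([np.sin(heading), np.cos(heading)])
            if np.linalg.norm(new - center) > radius:
                break
            segments.append((pos[0], pos[1], new[0], new[1], caliber))
            pos = new
            caliber *= params.taper
            if rng.random() < params.branch_prob:
                delta = rng.uniform(lo, hi)
                child = caliber * params.caliber_decay
                stack.append((pos.copy(), heading - delta / 2.0, child))
                stack.append((pos.copy(), heading + delta / 2.0, child))
                break
    return segments


def _stamp_tree(segments, size, radius_scale: float = 1.0):
    """Anti-aliased soft stroke map: 1 on centerlines, ->0 at radius + 0.5 px."""
    h, w = size
    soft = np.zeros((h, w), dtype=np.float32)
    for r0, c0, r1, c1, cal in segments:
        rad = cal * radius_scale
        length = float(np.hypot(r1 - r0, c1 - c0))
        n_pts = max(2, int(np.ceil(length / 0.5)) + 1)
        ts = np.linspace(0.0, 1.0, n_pts)
        for t in ts:
            pr, pc = r0 + t * (r1 - r0), c0 + t * (c1 - c0)
            lo_r = max(0, int(np.floor(pr - rad - 1)))
            hi_r = min(h, int(np.ceil(pr + rad + 2)))
            lo_c = max(0, int(np.floor(pc - rad - 1)))
            hi_c = min(w, int(np.ceil(pc + rad + 2)))
            if lo_r >= hi_r or lo_c >= hi_c:
                continue
            rr = np.arange(lo_r, hi_r, dtype=np.float32)[:, None]
            cc = np.arange(lo_c, hi_c, dtype=np.float32)[None, :]
            d = np.sqrt((rr - pr) ** 2 + (cc - pc) ** 2)
            alpha = np.clip(rad + 0.5 - d, 0.0, 1.0)
            patch = soft[lo_r:hi_r, lo_c:hi_c]
            np.maximum(patch, alpha, out=patch)
    return soft


def render_fundus(segments, params: SynthParams,
                  rng: np.random.Generator) -> Sample:
    """Rasterize a vessel tree into an (image, label, FOV) sample."""
    h, w = params.size
    center, radius = _fov_geometry(params)
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    fov = (dist <= radius).astype(np.uint8)

    soft = _stamp_tree(segments, params.size)
    label = ((soft >= 0.5) & (fov == 1)).astype(np.uint8)

    # background: base color * radial illumination field + low-frequency texture
    illum = 1.0 - params.illumination * np.clip(dist / radius, 0.0, 1.2) ** 2
    tex = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(h, w) / 16.0)
    ptp = tex.max() - tex.min()
    if ptp > 0:
        tex = (tex - tex.min()) / ptp - 0.5
    shade = (illum + 2.0 * params.texture * tex).astype(np.float32)

    img = np.empty((h, w, 3), dtype=np.float32)
    for ch, base in enumerate(params.base_color):
        img[..., ch] = base * shade
    img *= 1.0 - params.vessel_contrast * soft[..., None]
    if params.central_reflex:
        reflex = _stamp_tree(segments, params.size, radius_scale=0.3)
        img *= 1.0 + 0.6 * params.vessel_contrast * reflex[..., None]
    img += rng.normal(0.0, params.noise_sd, img.shape)
    img *= np.where(fov[..., None] == 1, 1.0, 0.04)
    img = np.clip(img, 0.0, 1.0)
    image = np.floor(img * 255.0 + 0.5).astype(np.uint8)
    return Sample(image=image, label=label, fov=fov, native_size=(h, w))


def make_sample(params: SynthParams, seed: int, index: int = 0) -> Sample:
    """One deterministic sample; the tree stream depends only on tree params."""
    rng_tree = np.random.default_rng([seed, index, 0])
    rng_app = np.random.default_rng([seed, index, 1])
    return render_fundus(sample_vessel_tree(params, rng_tree), params, rng_app)


def make_samples(n: int, preset: str = "source", seed: int = 0,
                 params: SynthParams | None = None) -> list[Sample]:
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or preset_params(preset)
    return [make_sample(params, seed, i) for i in range(n)]


def default_splits(n: int) -> list[str]:
    """70/15/15 train/val/test with at least one val and test image when n >= 3."""
    n_test = max(1, int(round(0.15 * n))) if n >= 3 else 0
    n_val = max(1, int(round(0.15 * n))) if n >= 3 else 0
    n_train = n - n_val - n_test
    return ["train"] * n_train + ["val"] * n_val + ["test"] * n_test


def make_dataset(n: int, preset: str, seed: int, out_dir,
                 splits: list[str] | None = None) -> pd.DataFrame:
    """Write n samples as PNGs plus a manifest CSV; fully reproducible."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = preset_params(preset)
    splits = splits or default_splits(n)
    if len(splits) != n:
        raise ValueError("splits must have one tag per sample")
    rows = []
    for i in range(n):
        s = make_sample(params, seed, i)
        stem = f"{preset}_{seed:04d}_{i:04d}"
        paths = {"image_path": out / f"{stem}_img.png",
                 "label_path": out / f"{stem}_label.png",
                 "fov_path": out / f"{stem}_fov.png"}
        iio.imwrite(paths["image_path"], s.image)
        iio.imwrite(paths["label_path"], (s.label * 255).astype(np.uint8))
        iio.imwrite(paths["fov_path"], (s.fov * 255).astype(np.uint8))
        rows.append({k: str(v) for k, v in paths.items()} | {"split": splits[i]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
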