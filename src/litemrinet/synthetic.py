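"""Synthetic MRI-like tumor slices and the image+mask PNG pipeline.

The generator emulates the structure of FLAIR-style 2-D tumor slices: a
dark background, a bright smooth-textured elliptical brain, and a single
connected irregular tumor blob occupying a small fraction of the brain
(the small-target regime).  Optionally a dark "hole" is carved inside the
tumor — an intensity feature only: hole pixels keep label 1 in the mask,
matching datasets where necrotic cores remain part of the tumor label.

Masks are exact tumor supports with background 0 and tumor 1.  Loading
applies the evaluation pipeline conventions: proportional resize of the
longest side to the target with symmetric zero padding to a square, area
interpolation for images, nearest-neighbor for masks, and binarization
of any nonzero mask value to 1.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["SyntheticConfig", "SamplePair", "generate_sample", "generate_dataset",
           "load_pair", "save_pair", "load_manifest"]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Distributional knobs for generated slices.

    ``tumor_area_range`` is a fraction of *brain* pixels; its upper bound
    must stay below 0.25 (the small-target contract).
    """

    image_size: int = 256
    brain_axes_range: tuple[float, float] = (0.28, 0.42)
    tumor_area_range: tuple[float, float] = (0.005, 0.05)
    hole_probability: float = 0.2
    noise_sigma: float = 0.02
    texture_scale: float = 12.0
    background_intensity: float = 0.05
    brain_intensity: float = 0.45
    tumor_intensity: float = 0.85
    hole_intensity: float = 0.10
    texture_amplitude: float = 0.08
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.tumor_area_range
        if not (0 < lo < hi):
            raise ValueError(f"tumor_area_range must be increasing positive, got {self.tumor_area_range}")
        if hi >= 0.25:
            raise ValueError(
                f"tumor_area_range upper bound {hi} violates the small-target "
                "contract (< 0.25 of brain pixels)")
        for name in ("brain_axes_range",):
            a, b = getattr(self, name)
            if not (0 < a <= b < 1):
                raise ValueError(f"{name} fractions must lie in (0,1), got {(a, b)}")
        if not 0 <= self.hole_probability <= 1:
            raise ValueError("hole_probability must be in [0,1]")


@dataclasses.dataclass
class SamplePair:
    """An image in [0,1] with its binary tumor mask."""

    image: np.ndarray  # (S, S, 3) float32
    mask: np.ndarray   # (S, S) uint8 in {0,1}
    tumor_fraction: float = 0.0  # of brain pixels


def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float,
                  angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - cx
    y = yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x * ca + y * sa) / ax
    v = (-x * sa + y * ca) / ay
    return u * u + v * v <= 1.0


def _star_blob(size: int, cx: float, cy: float, r0: float,
               coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Star-convex blob: radius varies with angle, so it stays connected."""
    yy, xx = np.mgrid[0:size, 0:size]
    x = xx - cx
    y = yy - cy
    theta = np.arctan2(y, x)
    radius = np.ones_like(theta) * r0
    for k, (a, phi) in enumerate(zip(coeffs, phases), start=2):
        radius = radius + r0 * a * np.cos(k * theta + phi)
    return x * x + y * y <= np.maximum(radius, 1.0) ** 2


def _texture(size: int, scale: float, amplitude: float,
             rng: np.random.Generator) -> np.ndarray:
    if amplitude <= 0 or scale <= 0:
        return np.zeros((size, size))
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    s = smooth.std()
    return amplitude * smooth / s if s > 0 else np.zeros((size, size))


def generate_sample(cfg: SyntheticConfig | None = None,
                    rng: np.random.Generator | int | None = None) -> SamplePair:
    """Draw one image/mask pair.

    Deterministic for a fixed ``rng`` seed; the mask is the exact support
    of the tumor blob (holes included).
    """
    cfg = cfg or SyntheticConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    s = cfg.image_size

    # brain ellipse
    ax = rng.uniform(*cfg.brain_axes_range) * s
    ay = rng.uniform(*cfg.brain_axes_range) * s
    cx = s / 2 + rng.uniform(-0.03, 0.03) * s
    cy = s / 2 + rng.uniform(-0.03, 0.03) * s
    angle = rng.uniform(0, np.pi)
    brain = _ellipse_mask(s, cx, cy, ax, ay, angle)
    n_brain = int(brain.sum())

    # tumor blob: rejection-sample a center, match the target area fraction
    target = rng.uniform(*cfg.tumor_area_range)
    coeffs = rng.normal(0.0, 0.10, size=4).clip(-0.3, 0.3)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    r0 = np.sqrt(target * n_brain / np.pi)
    if r0 >= min(ax, ay):
        raise ValueError("infeasible geometry: tumor radius exceeds brain axes")
    tumor = None
    for _ in range(30):
        t = rng.uniform(0, 2 * np.pi)
        rr = np.sqrt(rng.uniform(0, 1))
        tcx = cx + 0.55 * rr * ax * np.cos(angle) * np.cos(t) - 0.55 * rr * ay * np.sin(angle) * np.sin(t)
        tcy = cy + 0.55 * rr * ax * np.sin(angle) * np.cos(t) + 0.55 * rr * ay * np.cos(angle) * np.sin(t)
        r = r0
        for _ in range(8):  # rescale until the pixelated area hits the band
            blob = _star_blob(s, tcx, tcy, r, coeffs, phases)
            frac = blob.sum() / n_brain
            lo, hi = cfg.tumor_area_range
            if lo <= frac <= hi:
                break
            r *= np.sqrt(max(target / max(frac, 1e-9), 0.25))
        if (blob & ~brain).sum() == 0 and lo <= frac <= hi and blob.any():
            tumor = blob
            break
    if tumor is None:
        raise ValueError("infeasible geometry: could not place tumor inside brain")
    tumor_fraction = float(tumor.sum() / n_brain)

    # intensities
    img = np.full((s, s), cfg.background_intensity)
    img[brain] = cfg.brain_intensity
    img += _texture(s, cfg.texture_scale, cfg.texture_amplitude, rng) * brain
    img[tumor] = cfg.tumor_intensity + rng.uniform(-0.05, 0.05)

    if rng.uniform() < cfg.hole_probability:
        hr = np.sqrt(float(tumor.sum()) / np.pi) * rng.uniform(0.25, 0.45)
        hole = _ellipse_mask(s, tcx + rng.uniform(-1, 1), tcy + rng.uniform(-1, 1),
                             hr, hr, 0.0) & tumor
        img[hole] = cfg.hole_intensity  # intensity only; label stays 1

    rgb = np.repeat(img[:, :, None], 3, axis=2)
    if cfg.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, cfg.noise_sigma, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0).astype(np.float32)

    return SamplePair(image=rgb, mask=tumor.astype(np.uint8),
                      tumor_fraction=tumor_fraction)


def save_pair(pair: SamplePair, image_path, mask_path) -> None:
    """Write 8-bit PNGs: 3-channel image, single-channel {0,1} mask."""
    img8 = np.clip(np.round(pair.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="RGB").save(image_path)
    Image.fromarray(pair.mask.astype(np.uint8), mode="L").save(mask_path)


def generate_dataset(n: int, cfg: SyntheticConfig | None = None,
                     seed: int = 0, out_dir=None) -> list[dict]:
    """Generate ``n`` pairs; write PNGs + a CSV manifest if ``out_dir`` given.

    Each sample uses an RNG stream derived from ``(seed, index)``, so any
    subset is reproducible independently of the rest.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cfg = cfg or SyntheticConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        pair = generate_sample(cfg, rng)
        row = {"image_path": f"img_{i:04d}.png", "mask_path": f"mask_{i:04d}.png",
               "tumor_fraction": round(pair.tumor_fraction, 6), "seed_index": i,
               "pair": pair}
        if out is not None:
            save_pair(pair, out / row["image_path"], out / row["mask_path"])
        manifest.append(row)
    if out is not None:
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["image_path", "mask_path",
                                               "tumor_fraction", "seed_index"])
            w.writeheader()
            for row in manifest:
                w.writerow({k: row[k] for k in w.fieldnames})
    return manifest


def load_manifest(directory) -> list[tuple[Path, Path]]:
    """Read a manifest.csv back as (image_path, mask_path) pairs."""
    directory = Path(directory)
    pairs = []
    with open(directory / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pairs.append((directory / row["image_path"], directory / row["mask_path"]))
    return pairs


def _proportional_resize(im: Image.Image, target: int,
                         resample: Image.Resampling) -> Image.Image:
    """Scale the longest side to ``target``, pad the shorter side to square."""
    w, h = im.size
    scale = target / max(w, h)
    nw = max(1, round(w * scale))
    nh = max(1, round(h * scale))
    resized = im.resize((nw, nh), resample)
    canvas = Image.new(im.mode, (target, target), 0)
    canvas.paste(resized, ((target - nw) // 2, (target - nh) // 2))
    return canvas


def load_pair(image_path, mask_path, target_size: int = 256) -> SamplePair:
    """Load an image/mask PNG pair through the evaluation pipeline.

    Images are area-interpolated and scaled to [0,1]; masks are resized
    with nearest-neighbor and binarized (any nonzero value becomes 1).
    """
    try:
        im = Image.open(image_path).convert("RGB")
    except OSError as e:
        raise OSError(f"cannot read image {image_path}: {e}") from e
    try:
        mk = Image.open(mask_path)
    except OSError as e:
        raise OSError(f"cannot read mask {mask_path}: {e}") from e
    if mk.mode not in ("L", "P", "I", "I;16", "1"):
        raise OSError(f"mask {mask_path} must be single-channel, got mode {mk.mode}")
    mk = mk.convert("I")

    im = _proportional_resize(im, target_size, Image.Resampling.BOX)
    mk = _proportional_resize(mk, target_size, Image.Resampling.NEAREST)

    image = np.asarray(im, dtype=np.float32) / 255.0
    mask = (np.asarray(mk) > 0).astype(np.uint8)
    frac = float(mask.mean())
    return SamplePair(image=image, mask=mask, tumor_fraction=frac)
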