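"""Seeded generator of synthetic iodine-stained colposcopy-like images.

Real Lugol's-iodine colposcopy shows glycogen-rich normal epithelium stained
brown/black and suspicious (glycogen-poor) regions left mustard-yellow or
unstained, with irregular low-contrast boundaries, specular glare from the
wet surface, and a circular illuminated field.  This module emulates that
appearance contract so the segmentation pipeline can be exercised end to end:

* lesions are unions of star-convex blobs whose radii are modulated by a
  random low-order Fourier series (``boundary_roughness`` scales the
  modulation);
* the background is rendered around a brown base colour, lesion pixels
  around mustard-yellow, pulled toward the background by ``1 - contrast``;
* Gaussian blur softens boundaries, a radial vignette and a dark circular
  surround mimic the colposcope field, glare is painted as near-white
  ellipses, and additive Gaussian noise finishes the image.

The colours and the yellow-index separability rule are constructions for
benchmarking, NOT clinically calibrated.  Everything is a pure function of
(params, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

BG_BASE = np.array([110.0, 60.0, 40.0])       # stained epithelium (brown)
LESION_BASE = np.array([200.0, 170.0, 60.0])  # unstained lesion (mustard)
GLARE_VALUE = 252.0
FIELD_RADIUS = 0.48      # circular colposcope field, fraction of min(H, W)
SURROUND_DIM = 0.12      # brightness factor outside the field


@dataclass
class SynthParams:
    """Appearance and geometry dials for one synthetic sample."""

    size: tuple[int, int] = (224, 224)
    n_lesions: int | tuple[int, int] = (1, 4)
    lesion_area_fraction: tuple[float, float] = (0.05, 0.40)
    boundary_roughness: float = 0.25
    contrast: float = 0.8
    glare_count: int | tuple[int, int] = (1, 3)
    blur_sigma: float = 1.2
    noise_sd: float = 6.0
    vignette_strength: float = 0.35
    color_jitter: float = 10.0

    def validate(self) -> None:
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("lesion_area_fraction must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if min(self.size) < 16:
            raise ValueError("size too small")

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class LabeledSample:
    """8-bit RGB image (H,W,3) + binary lesion mask (H,W), lesion = 1."""

    image: np.ndarray
    mask: np.ndarray
    seed: int


def _count(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, tuple):
        return int(rng.integers(spec[0], spec[1] + 1))
    return int(spec)


def _star_blob(center: tuple[float, float], radius: float, roughness: float,
               shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Rasterise one star-convex blob with Fourier-modulated radius."""
    theta = np.linspace(0.0, 2 * np.pi, 180, endpoint=False)
    mod = np.zeros_like(theta)
    for k in range(2, 6):   # low-order harmonics: lobed but smooth outlines
        amp = rng.normal(0.0, 1.0 / k)
        phase = rng.uniform(0.0, 2 * np.pi)
        mod += amp * np.cos(k * theta + phase)
    mod = mod / (np.abs(mod).max() + 1e-9)
    r = radius * (1.0 + roughness * mod)
    r = np.clip(r, 0.2 * radius, None)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


class RejectionBudgetError(RuntimeError):
    pass


def sample_lesion_mask(params: SynthParams,
                       rng: np.random.Generator,
                       max_tries: int = 200) -> np.ndarray:
    """Union of star-convex blobs, rejection-sampled so the foreground
    fraction falls inside ``params.lesion_area_fraction``."""
    params.validate()
    H, W = params.size
    lo, hi = params.lesion_area_fraction
    placement_r = 0.32 * min(H, W)    # keep lesions inside the lit field
    cy, cx = H / 2.0, W / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    # lesions only exist inside the illuminated colposcope field
    lit = np.hypot(yy - cy, xx - cx) <= (FIELD_RADIUS - 0.02) * min(H, W)
    for attempt in range(max_tries):
        n = _count(params.n_lesions, rng)
        target = rng.uniform(lo, hi)
        # split the target area across blobs; radius from a disc of that area
        weights = rng.dirichlet(np.ones(n)) if n > 1 else np.array([1.0])
        mask = np.zeros((H, W), dtype=bool)
        centers: list[tuple[float, float]] = []
        for wgt in weights:
            radius = float(np.sqrt(wgt * target * H * W / np.pi))
            for _ in range(20):   # prefer centres spread apart
                ang = rng.uniform(0, 2 * np.pi)
                rad = placement_r * np.sqrt(rng.uniform())
                c = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
                if all(np.hypot(c[0] - o[0], c[1] - o[1]) > radius
                       for o in centers):
                    break
            centers.append(c)
            mask |= _star_blob(c, radius, params.boundary_roughness,
                               (H, W), rng)
        mask &= lit
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask
    raise RejectionBudgetError(
        f"no mask with foreground fraction in [{lo}, {hi}] after "
        f"{max_tries} tries (last fraction {frac:.3f})")


def render_image(mask: np.ndarray, params: SynthParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Render an 8-bit RGB image for a lesion mask."""
    params.validate()
    H, W = params.size
    if mask.shape != (H, W):
        raise ValueError(f"mask shape {mask.shape} != size {(H, W)}")
    j = params.color_jitter
    bg = BG_BASE + rng.uniform(-j, j, size=3)
    lesion = LESION_BASE + rng.uniform(-j, j, size=3)
    lesion = bg + params.contrast * (lesion - bg)

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = bg
    img[mask] = lesion

    # gentle multiplicative texture so the stain is not perfectly flat
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (H, W)), 6.0)
    tex = 1.0 + 0.08 * tex / (np.abs(tex).max() + 1e-9)
    img *= tex[..., None]

    if params.blur_sigma > 0:
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c],
                                                  params.blur_sigma)

    # circular colposcope field + radial vignette
    yy, xx = np.mgrid[0:H, 0:W]
    rr = np.hypot(yy - H / 2.0, xx - W / 2.0)
    field = rr <= FIELD_RADIUS * min(H, W)
    vign = 1.0 - params.vignette_strength * (rr / (FIELD_RADIUS * min(H, W))) ** 2
    vign = np.clip(vign, 0.0, 1.0)
    img *= np.where(field, vign, SURROUND_DIM)[..., None]

    # specular glare: near-white ellipses inside the field (post-vignette so
    # highlights stay saturated, as real reflections do)
    for _ in range(_count(params.glare_count, rng)):
        gy = rng.uniform(0.25 * H, 0.75 * H)
        gx = rng.uniform(0.25 * W, 0.75 * W)
        a = rng.uniform(0.01, 0.03) * min(H, W)
        b = a * rng.uniform(1.0, 2.5)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - gx) * ca + (yy - gy) * sa
        v = -(xx - gx) * sa + (yy - gy) * ca
        inside = (u / b) ** 2 + (v / a) ** 2 <= 1.0
        img[inside] = GLARE_VALUE

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_sample(params: SynthParams, seed: int) -> LabeledSample:
    rng = np.random.default_rng(seed)
    mask = sample_lesion_mask(params, rng)
    image = render_image(mask, params, rng)
    return LabeledSample(image=image, mask=mask.astype(np.uint8), seed=seed)


def generate_samples(n: int, params: SynthParams, seed: int) -> list[LabeledSample]:
    """n samples from independent child streams of one master seed."""
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [generate_sample(params, int(s)) for s in seeds]


def yellow_index(image: np.ndarray) -> np.ndarray:
    """R + G - 2B: high for mustard-yellow lesion, low for brown stain."""
    img = image.astype(np.float64)
    return img[..., 0] + img[..., 1] - 2.0 * img[..., 2]


def yellow_index_mask(image: np.ndarray, threshold: float = 170.0) -> np.ndarray:
    """Fixed colour-threshold segmenter used to certify separability."""
    return (yellow_index(image) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------


def generate_dataset(n: int, params: SynthParams, out_dir: str | Path,
                     seed: int, split_ratio: float = 0.9) -> Path:
    """Write n image/mask PNG pairs plus a CSV manifest; returns its path.

    ``split_ratio`` is the train fraction (default 9:1 train:test); the split
    assignment is a seeded random permutation.
    """
    if n < 2:
        raise ValueError("need n >= 2 to form a train/test split")
    if not 0.0 < split_ratio < 1.0:
        raise ValueError("split_ratio must lie in (0, 1)")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    samples = generate_samples(n, params, seed)
    n_train = min(int(round(n * split_ratio)), n - 1)
    n_train = max(n_train, 1)
    order = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:]] = "test"

    width = max(4, len(str(n - 1)))
    lines = ["id,image_path,mask_path,split,seed,params_hash"]
    phash = params.hash()
    for i, s in enumerate(samples):
        sid = f"{i:0{width}d}"
        img_rel = f"images/{sid}.png"
        msk_rel = f"masks/{sid}.png"
        Image.fromarray(s.image).save(out / img_rel)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out / msk_rel)
        lines.append(f"{sid},{img_rel},{msk_rel},{split[i]},{s.seed},{phash}")
    manifest = out / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def load_manifest(manifest: str | Path) -> list[dict]:
    manifest = Path(manifest)
    rows = []
    lines = manifest.read_text().strip().split("\n")
    header = lines[0].split(",")
    for line in lines[1:]:
        rows.append(dict(zip(header, line.split(","))))
    return rows


def load_samples(manifest: str | Path, split: str | None = None) -> list[LabeledSample]:
    manifest = Path(manifest)
    root = manifest.parent
    out = []
    missing = []
    for row in load_manifest(manifest):
        if split is not None and row["split"] != split:
            continue
        ipath, mpath = root / row["image_path"], root / row["mask_path"]
        if not ipath.exists() or not mpath.exists():
            missing.append(row["id"])
            continue
        image = np.asarray(Image.open(ipath).convert("RGB"))
        mask = (np.asarray(Image.open(mpath).convert("L")) >= 128).astype(np.uint8)
        out.append(LabeledSample(image=image, mask=mask, seed=int(row["seed"])))
    if missing:
        raise IOError(f"missing image/mask files for ids: {missing}")
    return out
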