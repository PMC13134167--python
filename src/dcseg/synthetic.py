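"""Seeded generation of histology-like image patches and mosaics.

Real H&E patches show a textured eosin-pink background with irregular,
more basophilic (purple) tumor regions.  The generator emulates exactly
that much structure and no more: each patch is a noisy background color
plus one or more irregular blobs — ellipses whose radius is perturbed by
low-frequency angular noise — with a per-class mean color, per-patch
stain jitter and per-pixel texture noise.  Masks store the class index
per pixel (0 = background).

In two-class mode every blob is class 1 ("tumor"); in five-class mode
blobs cycle through classes 1-4 over background 0, emulating a
tumor/stroma/lymphocyte/necrosis labeling.

All randomness flows through the explicit seed of the spec or call; the
same spec and seed reproduce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile

__all__ = ["SyntheticPatchSpec", "PatchDataset", "SyntheticWSI",
           "generate_patch", "generate_patches", "make_ssl_split",
           "generate_wsi", "save_dataset", "save_wsi", "DEFAULT_PALETTE",
           "FIVE_CLASS_PALETTE"]

# Background eosin pink, then tumor purple; extended colors for 5-class mode.
DEFAULT_PALETTE = ((0.88, 0.80, 0.86), (0.58, 0.40, 0.66))
FIVE_CLASS_PALETTE = ((0.88, 0.80, 0.86), (0.58, 0.40, 0.66),
                      (0.82, 0.58, 0.70), (0.45, 0.35, 0.75),
                      (0.70, 0.62, 0.50))


@dataclass
class SyntheticPatchSpec:
    height: int = 64
    width: int = 64
    n_classes: int = 2
    blob_count_range: tuple = (1, 3)
    blob_radius_range: tuple = (8, 16)
    texture_noise_sd: float = 0.08
    stain_jitter_sd: float = 0.04
    class_palette: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValueError("patch must be at least 16x16")
        if self.n_classes < 2:
            raise ValueError("need at least background + one foreground class")
        lo, hi = self.blob_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("blob_radius_range must be a positive interval")
        if 2 * hi > min(self.height, self.width):
            raise ValueError(
                f"blob diameter {2 * hi} exceeds patch size "
                f"{min(self.height, self.width)}")
        clo, chi = self.blob_count_range
        if clo < 0 or chi < clo:
            raise ValueError("blob_count_range must be a nonnegative interval")
        if self.class_palette is None:
            base = FIVE_CLASS_PALETTE if self.n_classes > 2 else DEFAULT_PALETTE
            if self.n_classes > len(base):
                raise ValueError("provide class_palette for n_classes > 5")
            self.class_palette = tuple(base[:self.n_classes])
        elif len(self.class_palette) < self.n_classes:
            raise ValueError("class_palette shorter than n_classes")


@dataclass
class PatchDataset:
    """Labeled/unlabeled pools of a semi-supervised split.

    ``labeled_items`` holds (image, mask) pairs; ``unlabeled_items`` holds
    images whose masks were withheld.  ``labeled_indices`` records which
    positions of the source list kept their masks.
    """
    labeled_items: list
    unlabeled_items: list
    n_l: int
    n_u: int
    labeled_indices: tuple = ()
    unlabeled_indices: tuple = ()


@dataclass
class SyntheticWSI:
    image: np.ndarray
    mask: np.ndarray
    magnification_factor: float = 4.0

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if self.magnification_factor < 1:
            raise ValueError("magnification_factor must be >= 1")


def _blob_mask(rng, h, w, cy, cx, radius) -> np.ndarray:
    """Irregular blob: ellipse with low-frequency radial perturbation."""
    aspect = rng.uniform(0.7, 1.3)
    theta0 = rng.uniform(0, 2 * np.pi)
    n_harm = 3
    amp = rng.uniform(0.05, 0.18, n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * dx + st * dy
    v = (-st * dx + ct * dy) / aspect
    r = np.hypot(u, v)
    ang = np.arctan2(v, u)
    pert = np.ones_like(ang)
    for k in range(n_harm):
        pert += amp[k] * np.sin((k + 2) * ang + phase[k])
    return r <= radius * pert


def generate_patch(spec: SyntheticPatchSpec, seed: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair; image is HxWx3 float in [0,1], mask int."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.int64)
    n_blobs = int(rng.integers(spec.blob_count_range[0],
                               spec.blob_count_range[1] + 1))
    rlo, rhi = spec.blob_radius_range
    for b in range(n_blobs):
        radius = rng.uniform(rlo, rhi)
        cy = rng.uniform(radius, h - radius)
        cx = rng.uniform(radius, w - radius)
        blob = _blob_mask(rng, h, w, cy, cx, radius)
        cls = 1 if spec.n_classes == 2 else 1 + b % (spec.n_classes - 1)
        mask[blob] = cls
    palette = np.asarray(spec.class_palette, dtype=np.float64)
    jitter = rng.normal(0.0, spec.stain_jitter_sd, 3)
    image = palette[mask] + jitter
    # low-frequency texture: coarse noise field bilinearly blown up
    coarse = rng.normal(0.0, spec.texture_noise_sd,
                        (max(h // 8, 2), max(w // 8, 2), 3))
    reps_y = int(np.ceil(h / coarse.shape[0]))
    reps_x = int(np.ceil(w / coarse.shape[1]))
    texture = np.repeat(np.repeat(coarse, reps_y, axis=0), reps_x, axis=1)
    image += texture[:h, :w]
    image += rng.normal(0.0, spec.texture_noise_sd, (h, w, 3))
    return np.clip(image, 0.0, 1.0).astype(np.float32), mask


def generate_patches(spec: SyntheticPatchSpec, n: int, seed: int | None = None
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """``n`` independent patches; per-patch seeds are spawned from one root."""
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    return [generate_patch(spec, seed=np.random.default_rng(child).integers(2**31))
            for child in root.spawn(n)]


def make_ssl_split(patches: list, labeled_fraction: float, seed: int
                   ) -> PatchDataset:
    """Withhold masks from all but round(labeled_fraction * N) patches.

    The partition depends on ``seed`` only; the labeled and unlabeled index
    sets are disjoint and exhaustive.
    """
    if not patches:
        raise ValueError("empty patch list")
    if not (0.0 < labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must lie in (0, 1]")
    n = len(patches)
    n_l = int(np.floor(labeled_fraction * n + 0.5))
    n_l = max(1, min(n, n_l))
    order = np.random.default_rng(seed).permutation(n)
    lab_idx = tuple(int(i) for i in sorted(order[:n_l]))
    unl_idx = tuple(int(i) for i in sorted(order[n_l:]))
    labeled = [patches[i] for i in lab_idx]
    unlabeled = [patches[i][0] for i in unl_idx]
    return PatchDataset(labeled_items=labeled, unlabeled_items=unlabeled,
                        n_l=len(labeled), n_u=len(unlabeled),
                        labeled_indices=lab_idx, unlabeled_indices=unl_idx)


def generate_wsi(spec: SyntheticPatchSpec, grid: tuple[int, int],
                 seed: int | None = None) -> SyntheticWSI:
    """A (rows x cols)-tile mosaic with large blobs spanning tile borders.

    Blob radii are drawn at one-to-two tile sizes so that tiling,
    stitching and contour export are exercised across tile boundaries.
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = rows * spec.height, cols * spec.width
    tile = min(spec.height, spec.width)
    mask = np.zeros((h, w), dtype=np.int64)
    n_blobs = int(rng.integers(2, max(3, rows * cols // 4) + 1))
    for b in range(n_blobs):
        radius = rng.uniform(0.6 * tile, 1.2 * tile)
        cy = rng.uniform(radius * 0.5, h - radius * 0.5)
        cx = rng.uniform(radius * 0.5, w - radius * 0.5)
        blob = _blob_mask(rng, h, w, cy, cx, radius)
        cls = 1 if spec.n_classes == 2 else 1 + b % (spec.n_classes - 1)
        mask[blob] = cls
    palette = np.asarray(spec.class_palette, dtype=np.float64)
    image = palette[mask]
    image += rng.normal(0.0, spec.texture_noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SyntheticWSI(image=image, mask=mask)


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def save_dataset(ds: PatchDataset, out_dir) -> Path:
    """Write patches as 8-bit RGB PNG, masks as single-channel PNG (pixel
    value = class index) and a manifest of one ``path<TAB>flag`` line per
    item (flag ``labeled`` or ``unlabeled``).  Returns the manifest path.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    lines = []
    for j, (img, msk) in enumerate(ds.labeled_items):
        name = f"labeled_{j:05d}.png"
        Image.fromarray((img * 255).astype(np.uint8)).save(out / "images" / name)
        Image.fromarray(msk.astype(np.uint8), mode="L").save(out / "masks" / name)
        lines.append(f"images/{name}\tlabeled")
    for j, img in enumerate(ds.unlabeled_items):
        name = f"unlabeled_{j:05d}.png"
        Image.fromarray((img * 255).astype(np.uint8)).save(out / "images" / name)
        lines.append(f"images/{name}\tunlabeled")
    manifest = out / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def save_wsi(wsi: SyntheticWSI, image_path, mask_path=None):
    tifffile.imwrite(image_path, (wsi.image * 255).astype(np.uint8))
    if mask_path is not None:
        tifffile.imwrite(mask_path, wsi.mask.astype(np.uint8))
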