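"""Seeded generator of three-class H&E-like texture patches.

The classes mirror a lung-adenocarcinoma infiltration-grading task:

* ``normal`` — benign tissue: eosin-pink stroma with scattered
  hematoxylin-purple nuclei and no lesion.
* ``microinfiltration`` — lesion foci whose maximum diameter (Feret
  diameter of each connected component) is at most a configured threshold.
* ``infiltration`` — at least one lesion focus with maximum diameter
  strictly above the threshold.

Lesions are clusters of tubular motifs — random curved tubes with darker
rims and occasional ring (lumen) cross-sections — emulating the tubular,
columnar-elliptical structures of glandular lesions. The physical
"0.5 cm at 20x" rule is mapped to a pixel threshold (default a quarter of
the patch side); only the relative rule matters for exercising models.

The diameter invariants hold *by construction*: microinfiltration clusters
are clipped to discs strictly below the threshold and placed with disjoint
supports, while every infiltration patch contains one connected tube whose
endpoint pixels are laid farther apart than the threshold. Class
boundaries are deliberately confusable: micro diameters range up to the
threshold and infiltration diameters start just above it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "LABELS",
    "SyntheticPatchConfig",
    "GeneratedPatch",
    "generate_patch",
    "generate_dataset",
    "augment",
    "feret_diameter",
    "max_component_feret",
]

LABELS = ("infiltration", "microinfiltration", "normal")

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity for lesion components


@dataclass
class SyntheticPatchConfig:
    patch_size: int = 224
    diameter_threshold_px: int | None = None  # default: patch_size // 4
    n_lesions_range: dict = field(default_factory=lambda: {
        "infiltration": (1, 2), "microinfiltration": (1, 2)})
    tube_width_range: tuple[float, float] = (2.0, 3.5)  # at patch_size 224; scaled
    cluster_fill_range: tuple[float, float] = (0.25, 0.45)  # lesion-disc area fraction
    nucleus_density: float = 0.002  # nuclei per px^2 in stroma
    background_rgb: tuple[float, float, float] = (0.93, 0.80, 0.87)  # eosin pink
    nucleus_rgb: tuple[float, float, float] = (0.38, 0.24, 0.51)  # hematoxylin purple
    lesion_rgb: tuple[float, float, float] = (0.70, 0.48, 0.66)
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.diameter_threshold_px is None:
            self.diameter_threshold_px = self.patch_size // 4
        if not 0 < self.diameter_threshold_px < self.patch_size:
            raise ValueError("diameter_threshold_px must be positive and smaller than patch_size")
        if self.diameter_threshold_px < 8:
            raise ValueError("diameter_threshold_px too small to place any tubular motif")
        w_hi = self.tube_width_range[1] * self.patch_size / 224.0
        if 1.2 * self.diameter_threshold_px + 4 * w_hi + 4 > self.patch_size:
            raise ValueError("diameter_threshold_px too large: no room for an "
                             "above-threshold lesion focus inside the patch")
        for key, (lo, hi) in self.n_lesions_range.items():
            if key not in LABELS or lo < 1 or hi < lo:
                raise ValueError(f"invalid n_lesions_range entry {key}: ({lo}, {hi})")
        if not 0 < self.tube_width_range[0] <= self.tube_width_range[1]:
            raise ValueError("tube_width_range must be positive and ordered")
        if self.nucleus_density < 0 or self.noise_level < 0:
            raise ValueError("nucleus_density and noise_level must be >= 0")

    @property
    def scale(self) -> float:
        return self.patch_size / 224.0


@dataclass
class GeneratedPatch:
    image: np.ndarray  # (P, P, 3) uint8
    label: str
    lesion_mask: np.ndarray  # (P, P) bool
    provenance: dict


# ---------------------------------------------------------------------------
# geometry helpers


def _paint_disc(mask: np.ndarray, cy: float, cx: float, r: float):
    p = mask.shape[0]
    r = max(r, 0.6)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, p)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, p)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _paint_ring(mask: np.ndarray, cy: float, cx: float, r: float, thickness: float):
    p = mask.shape[0]
    y0, y1 = max(int(cy - r) - 2, 0), min(int(cy + r) + 3, p)
    x0, x1 = max(int(cx - r) - 2, 0), min(int(cx + r) + 3, p)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask[y0:y1, x0:x1] |= (d2 <= (r + thickness / 2) ** 2) & (d2 >= max(r - thickness / 2, 0) ** 2)


def _bezier(p0, p1, ctrl, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1


def _paint_tube(mask: np.ndarray, path: np.ndarray, width: float):
    for cy, cx in path:
        _paint_disc(mask, cy, cx, width / 2)


# ---------------------------------------------------------------------------
# lesion clusters


def _dense_cluster(mask: np.ndarray, center: np.ndarray, diameter: float,
                   config: SyntheticPatchConfig, rng: np.random.Generator):
    """A lesion focus: tubular/ring motifs packed into (and clipped to) a
    disc of the given diameter, filled to a sampled area fraction so focus
    area tracks focus diameter the way real glandular clusters do."""
    radius = diameter / 2.0
    p = mask.shape[0]
    work = np.zeros_like(mask)
    yy, xx = np.ogrid[:p, :p]
    disc = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    disc_area = max(int(disc.sum()), 1)
    target_fill = rng.uniform(*config.cluster_fill_range)
    w_lo, w_hi = config.tube_width_range
    for t in range(60):
        width = rng.uniform(w_lo, w_hi) * config.scale
        if t == 0:
            p0 = center + rng.uniform(-0.2, 0.2, 2) * radius  # a motif always survives the clip
        else:
            p0 = center + rng.uniform(-0.85, 0.85, 2) * radius
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.5, 1.4) * radius
        p1 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
        ctrl = (p0 + p1) / 2 + rng.normal(0, 0.15 * length, 2)
        _paint_tube(work, _bezier(p0, p1, ctrl, max(int(2 * length) + 2, 4)), width)
        if rng.random() < 0.5:
            _paint_ring(work, *((p0 + p1) / 2), rng.uniform(1.5, 3.5) * config.scale,
                        1.2 * config.scale)
        work &= disc  # every surviving pixel pair is at most `diameter` apart
        if work.sum() >= target_fill * disc_area:
            break
    mask |= work


def _infiltration_cluster(mask: np.ndarray, config: SyntheticPatchConfig,
                          rng: np.random.Generator):
    """A dense focus wider than the threshold: a connected tube spanning the
    focus disc pins the Feret diameter above the threshold by construction."""
    p = config.patch_size
    thr = config.diameter_threshold_px
    w_lo, w_hi = config.tube_width_range
    width = rng.uniform(w_lo, w_hi) * config.scale
    d = rng.uniform(1.2, min(1.6, (p - 4 * w_hi * config.scale - 4) / thr)) * thr
    margin = d / 2 + 2 * width + 2
    center = rng.uniform(margin, p - margin, 2)
    ang = rng.uniform(0, 2 * np.pi)
    half = d / 2 * np.array([np.sin(ang), np.cos(ang)])
    p0, p1 = center - half, center + half
    ctrl = center + rng.normal(0, 0.1 * d, 2)
    path = _bezier(p0, p1, ctrl, max(int(2 * d), 8))
    _paint_tube(mask, path, width)
    mask[int(round(p0[0])), int(round(p0[1]))] = True  # pin the extremes
    mask[int(round(p1[0])), int(round(p1[1]))] = True
    # fill the focus around the spanning tube
    _dense_cluster(mask, center, d, config, rng)


def _place_micro_centers(n: int, config: SyntheticPatchConfig, rng: np.random.Generator):
    """Cluster centers with pairwise-disjoint supporting discs."""
    p, thr = config.patch_size, config.diameter_threshold_px
    centers, diameters = [], []
    for _ in range(n):
        for _attempt in range(50):
            d = rng.uniform(0.45, 0.95) * thr
            margin = d / 2 + 2
            c = rng.uniform(margin, p - margin, 2)
            if all(np.hypot(*(c - c2)) > (d + d2) / 2 + 3 for c2, d2 in zip(centers, diameters)):
                centers.append(c)
                diameters.append(d)
                break
    return centers, diameters


# ---------------------------------------------------------------------------
# rendering


def _render(lesion_mask: np.ndarray, config: SyntheticPatchConfig,
            rng: np.random.Generator) -> np.ndarray:
    p = config.patch_size
    img = np.empty((p, p, 3), dtype=np.float64)
    img[:] = config.background_rgb
    # correlated stain texture
    tex = ndimage.gaussian_filter(rng.standard_normal((p, p)), sigma=max(p / 28, 2.0))
    tex /= max(np.abs(tex).max(), 1e-9)
    img += 0.05 * tex[:, :, None]
    # scattered stromal nuclei
    n_nuclei = rng.poisson(config.nucleus_density * p * p)
    nucleus = np.asarray(config.nucleus_rgb)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, p, 2)
        r = rng.uniform(1.0, 2.2) * config.scale
        spot = np.zeros((p, p), dtype=bool)
        _paint_disc(spot, cy, cx, r)
        img[spot] = 0.35 * img[spot] + 0.65 * nucleus
    if lesion_mask.any():
        lesion = np.asarray(config.lesion_rgb)
        img[lesion_mask] = 0.45 * img[lesion_mask] + 0.55 * lesion
        rim = lesion_mask & ~ndimage.binary_erosion(lesion_mask, structure=_EIGHT)
        img[rim] = 0.25 * img[rim] + 0.75 * nucleus  # dark columnar-cell rims
        # denser nuclei inside lesions
        ys, xs = np.nonzero(lesion_mask)
        for _ in range(max(len(ys) // 60, 1)):
            k = rng.integers(0, len(ys))
            spot = np.zeros((p, p), dtype=bool)
            _paint_disc(spot, ys[k] + rng.normal(0, 1), xs[k] + rng.normal(0, 1),
                        rng.uniform(1.0, 2.0) * config.scale)
            img[spot] = 0.3 * img[spot] + 0.7 * nucleus
    img += rng.normal(0.0, config.noise_level, img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


# ---------------------------------------------------------------------------
# public API


def generate_patch(label: str, config: SyntheticPatchConfig,
                   rng: np.random.Generator, provenance: dict | None = None) -> GeneratedPatch:
    """Draw one patch of the requested class. Deterministic in (config, rng state)."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    p = config.patch_size
    lesion_mask = np.zeros((p, p), dtype=bool)
    if label == "microinfiltration":
        lo, hi = config.n_lesions_range[label]
        centers, diameters = _place_micro_centers(int(rng.integers(lo, hi + 1)), config, rng)
        for c, d in zip(centers, diameters):
            _dense_cluster(lesion_mask, c, d, config, rng)
    elif label == "infiltration":
        lo, hi = config.n_lesions_range[label]
        n = int(rng.integers(lo, hi + 1))
        _infiltration_cluster(lesion_mask, config, rng)
        if n > 1:  # secondary small foci; the principal focus stays dominant
            centers, diameters = _place_micro_centers(n - 1, config, rng)
            for c, d in zip(centers, diameters):
                _dense_cluster(lesion_mask, c, d, config, rng)
    image = _render(lesion_mask, config, rng)
    return GeneratedPatch(image=image, label=label, lesion_mask=lesion_mask,
                          provenance=provenance or {})


def feret_diameter(mask: np.ndarray) -> float:
    """Maximum pairwise pixel distance within the largest (by area)
    connected component of a binary mask; 0.0 for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    labels, n = ndimage.label(mask, structure=_EIGHT)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    coords = np.argwhere(labels == (int(np.argmax(areas)) + 1))
    return _max_pairwise(coords)


def max_component_feret(mask: np.ndarray) -> float:
    """Maximum Feret diameter over *all* connected components."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    labels, n = ndimage.label(mask, structure=_EIGHT)
    return max(_max_pairwise(np.argwhere(labels == i)) for i in range(1, n + 1))


def _max_pairwise(coords: np.ndarray) -> float:
    pts = coords.astype(np.float64)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 100:  # diameter is attained on the convex hull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # collinear component
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def augment(image: np.ndarray, rng: np.random.Generator, *, p_hflip: float = 0.5,
            p_vflip: float = 0.5, p_rotate: float = 0.5, p_noise: float = 0.5,
            max_angle: float = 30.0, noise_level: float = 0.02,
            out_size: int | None = None) -> np.ndarray:
    """Training-time augmentation: random horizontal flip, vertical flip,
    rotation and noise overlay, then rescale to ``out_size`` (e.g. 224).
    ``out_size=None`` keeps the input size. Output dtype/range match input."""
    img = np.asarray(image)
    was_int = np.issubdtype(img.dtype, np.integer)
    out = img.astype(np.float64)
    draws = rng.random(3)
    if draws[0] < p_hflip:
        out = out[:, ::-1]
    if draws[1] < p_vflip:
        out = out[::-1, :]
    if draws[2] < p_rotate:
        angle = rng.uniform(-max_angle, max_angle)
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False, order=1, mode="reflect")
    if rng.random() < p_noise:
        out = out + rng.normal(0.0, noise_level * (255.0 if was_int else 1.0), out.shape)
    out = np.clip(out, 0, 255 if was_int else 1.0)
    if out_size is not None and out.shape[:2] != (out_size, out_size):
        pil = Image.fromarray(np.ascontiguousarray(out).astype(np.uint8) if was_int
                              else (out * 255).astype(np.uint8))
        out = np.asarray(pil.resize((out_size, out_size), Image.BILINEAR), dtype=np.float64)
        if not was_int:
            out = out / 255.0
    if was_int:
        return np.ascontiguousarray(out).round().astype(img.dtype)
    return np.ascontiguousarray(out).astype(img.dtype)


def _sample_seed(base_seed: int, label_idx: int, index: int) -> int:
    # stable, collision-free per-sample seed below 2**31
    h = hashlib.sha256(f"{base_seed}:{label_idx}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def generate_dataset(config: SyntheticPatchConfig, counts, out_dir,
                     split: float = 0.8, overwrite: bool = False) -> pd.DataFrame:
    """Write a folder-per-class PNG tree with a train/test split.

    ``counts`` is either an int (per class) or a {label: n} mapping. Returns
    the manifest (columns label, seed, diameter_px, split, path), which is
    also written to ``out_dir/manifest.csv``. Identical (config, counts)
    regenerate byte-identical files.
    """
    if isinstance(counts, int):
        counts = {label: counts for label in LABELS}
    if any(n < 1 for n in counts.values()):
        raise ValueError("counts must be >= 1 for every class")
    if not 0.0 < split <= 1.0:
        raise ValueError("split must be in (0, 1]")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{out_dir} already holds a dataset; pass overwrite=True")
    rows = []
    for label_idx, label in enumerate(LABELS):
        n = counts.get(label, 0)
        if n == 0:
            continue
        n_test = int(round((1.0 - split) * n))
        for i in range(n):
            seed = _sample_seed(config.seed, label_idx, i)
            patch = generate_patch(label, config, np.random.default_rng(seed),
                                   provenance={"seed": seed, "draw_index": i})
            part = "test" if i >= n - n_test else "train"
            rel = Path(part) / label / f"{label}_{i:05d}.png"
            dest = out_dir / rel
            dest.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(patch.image).save(dest)
            rows.append({"label": label, "seed": seed,
                         "diameter_px": round(max_component_feret(patch.lesion_mask), 3),
                         "split": part, "path": str(rel)})
    manifest = pd.DataFrame(rows, columns=["label", "seed", "diameter_px", "split", "path"])
    manifest.to_csv(manifest_path, index=False)
    return manifest
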