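"""Seeded generator of panicle-like oriented scenes with ground truth.

Real UAV rice-field imagery shows slender, bright, arbitrarily oriented
panicles (aspect ratio well above 1, 15-40 per 608 px tile) over a cluttered
green-brown canopy, with crossing/parallel/curved arrangements.  This module
emulates those geometric and statistical properties with textured 2-D
capsule strokes over procedural canopy clutter — deliberately not
photorealistic, but enough structure (orientation, elongation, density,
occlusion, background confusion) to exercise every downstream stage of the
pipeline offline: annotation conversion, tiling, training and rotated-box
evaluation.

Presets mirror the two flight heights (a 10 m preset scales object size by
3/10 relative to the 3 m preset) and two growth stages (the filling preset
raises density, overlap and gives panicles a golden hue).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from oeyolo.data_io import AnnotationRecord, records_to_yolo_obb, save_image
from oeyolo.geometry import OrientedBox, min_area_rect, polygon_iou

__all__ = ["SceneSpec", "PlacementError", "generate_scene", "generate_dataset",
           "sample_object_count", "PRESETS"]


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed under the overlap constraint."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic oriented scene.

    ``n_objects`` may be a fixed int or an inclusive (lo, hi) range.
    ``overlap_level`` bounds the pairwise polygon IoU of ground-truth boxes
    (enforced by rejection sampling).  ``height_preset`` "10m" rescales
    object dimensions by 3/10 relative to "3m"; ``stage_preset`` "filling"
    is denser and more overlapped than "heading".
    """

    image_size: int = 608
    n_objects: int | Tuple[int, int] = (15, 28)
    length_range: Tuple[float, float] = (60.0, 140.0)
    width_range: Tuple[float, float] = (10.0, 18.0)
    curvature_prob: float = 0.3
    overlap_level: float = 0.05
    background: float = 1.0
    height_preset: str = "3m"
    stage_preset: str = "heading"

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        lo, hi = self.count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_objects")
        if not (0.0 <= self.overlap_level < 1.0):
            raise ValueError("overlap_level must lie in [0, 1)")
        if self.length_range[0] <= 0 or self.width_range[0] <= 0:
            raise ValueError("object size ranges must be positive")

    @property
    def count_range(self) -> Tuple[int, int]:
        if isinstance(self.n_objects, int):
            return (self.n_objects, self.n_objects)
        return (int(self.n_objects[0]), int(self.n_objects[1]))

    @property
    def scale(self) -> float:
        """Object scale factor implied by the flight-height preset."""
        return 0.3 if self.height_preset == "10m" else 1.0


# study conditions for the four flight-height x growth-stage combinations
PRESETS: Dict[str, SceneSpec] = {
    "heading3m": SceneSpec(),
    "filling3m": SceneSpec(n_objects=(25, 40), overlap_level=0.15, stage_preset="filling"),
    "heading10m": SceneSpec(height_preset="10m"),
    "filling10m": SceneSpec(
        n_objects=(25, 40), overlap_level=0.15, stage_preset="filling", height_preset="10m"
    ),
}


def sample_object_count(spec: SceneSpec, rng: np.random.Generator) -> int:
    """Draw the per-scene object count (uniform over the inclusive range)."""
    lo, hi = spec.count_range
    return lo if lo == hi else int(rng.integers(lo, hi + 1))


def _background(size: int, intensity: float, rng: np.random.Generator) -> np.ndarray:
    """Green-brown canopy clutter: low-frequency color field + blade strokes
    + speckle."""
    from scipy import ndimage

    coarse = rng.uniform(0.0, 1.0, (size // 32 + 2, size // 32 + 2, 3))
    zoom = (size / coarse.shape[0], size / coarse.shape[1], 1)
    base = ndimage.zoom(coarse, zoom, order=1)[:size, :size]
    lo = np.array([30.0, 60.0, 20.0])
    hi = np.array([80.0, 130.0, 60.0])
    img = lo + base * (hi - lo)
    img += intensity * rng.normal(0.0, 9.0, img.shape)
    return img


def _draw_capsule(
    img: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    width: float,
    color: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Soft-edged textured capsule stroke from p0 to p1; returns its alpha
    mask over the full image (float in [0, 1])."""
    size = img.shape[0]
    r = width / 2.0
    x0 = max(int(min(p0[0], p1[0]) - r - 2), 0)
    x1 = min(int(max(p0[0], p1[0]) + r + 3), size)
    y0 = max(int(min(p0[1], p1[1]) - r - 2), 0)
    y1 = min(int(max(p0[1], p1[1]) + r + 3), size)
    full = np.zeros((size, size), dtype=np.float32)
    if x0 >= x1 or y0 >= y1:
        return full
    ys, xs = np.mgrid[y0:y1, x0:x1]
    pts = np.stack([xs + 0.5, ys + 0.5], axis=-1).astype(np.float64)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-9:
        dist = np.linalg.norm(pts - p0, axis=-1)
        t = np.zeros(dist.shape)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    alpha = np.clip(r - dist + 0.5, 0.0, 1.0).astype(np.float32)
    # grain: multiplicative speckle plus brighter spikelets along the axis
    grain = 1.0 + 0.3 * rng.normal(0.0, 1.0, alpha.shape) * (alpha > 0)
    spikelet = (rng.random(alpha.shape) < 0.08) & (alpha > 0.5)
    window = img[y0:y1, x0:x1]
    tinted = color[None, None, :] * np.clip(grain, 0.4, 1.6)[..., None]
    tinted = np.where(spikelet[..., None], np.minimum(tinted * 1.35, 255.0), tinted)
    img[y0:y1, x0:x1] = window * (1.0 - alpha[..., None]) + tinted * alpha[..., None]
    full[y0:y1, x0:x1] = alpha
    return full


def _panicle_color(stage: str, rng: np.random.Generator) -> np.ndarray:
    if stage == "filling":  # golden, grain-laden
        return np.array(
            [rng.uniform(185, 220), rng.uniform(160, 190), rng.uniform(80, 115)]
        )
    # heading: pale yellow-green against the darker canopy
    return np.array([rng.uniform(150, 190), rng.uniform(175, 205), rng.uniform(85, 120)])


def _mask_box(mask: np.ndarray) -> OrientedBox:
    """Minimum-area oriented rectangle tightly enclosing a soft mask."""
    from scipy.spatial import ConvexHull

    ys, xs = np.nonzero(mask > 0.5)
    pts = np.stack([xs + 0.5, ys + 0.5], axis=-1).astype(float)
    hull = ConvexHull(pts)
    return min_area_rect(pts[hull.vertices])


def generate_scene(
    spec: SceneSpec, seed: int
) -> Tuple[np.ndarray, List[AnnotationRecord]]:
    """Render one scene; returns (uint8 RGB image, ground-truth records).

    Objects are textured capsules (optionally bent into two joined
    segments); each ground-truth box is the minimum-area rectangle of the
    object's rendered mask.  Rejection sampling enforces pairwise polygon
    IoU of ground-truth boxes <= ``spec.overlap_level``.  Identical
    (spec, seed) pairs give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    size = spec.image_size
    img = _background(size, spec.background, rng)
    n = sample_object_count(spec, rng)

    # non-annotated clutter blades confusable with targets
    n_blades = int(rng.integers(6, 14) * spec.background)
    for _ in range(n_blades):
        c = rng.uniform(0, size, 2)
        ang = rng.uniform(-math.pi, math.pi)
        length = rng.uniform(30, 90) * spec.scale
        d = np.array([math.cos(ang), math.sin(ang)]) * length / 2
        shade = np.array([rng.uniform(20, 55), rng.uniform(60, 110), rng.uniform(20, 50)])
        _draw_capsule(img, c - d, c + d, rng.uniform(2, 5) * spec.scale, shade, rng)

    placed_boxes: List[OrientedBox] = []
    records: List[AnnotationRecord] = []
    margin = 8.0 * spec.scale
    for obj in range(n):
        for attempt in range(1000):
            length = rng.uniform(*spec.length_range) * spec.scale
            width = rng.uniform(*spec.width_range) * spec.scale
            theta = rng.uniform(-math.pi / 2, math.pi / 2)
            center = rng.uniform(margin, size - margin, 2)
            bent = rng.random() < spec.curvature_prob
            axis = np.array([math.cos(theta), math.sin(theta)])
            if bent:
                bend = rng.uniform(0.15, 0.45) * rng.choice([-1.0, 1.0])
                a0 = theta - bend / 2
                a1 = theta + bend / 2
                half = length / 2.0
                mid = center
                p0 = mid - np.array([math.cos(a0), math.sin(a0)]) * half
                p1 = mid + np.array([math.cos(a1), math.sin(a1)]) * half
                segs = [(p0, mid), (mid, p1)]
            else:
                d = axis * length / 2.0
                segs = [(center - d, center + d)]
            # analytic proposal box from the stroke geometry (pre-render)
            pts = []
            for a, b in segs:
                dd = b - a
                nrm = np.array([-dd[1], dd[0]])
                nrm = nrm / max(np.linalg.norm(nrm), 1e-9) * (width / 2.0 + 0.5)
                along = dd / max(np.linalg.norm(dd), 1e-9) * (width / 2.0 + 0.5)
                pts += [a - nrm - along, a + nrm - along, b - nrm + along, b + nrm + along]
            proposal = min_area_rect(pts)
            if not (0 <= proposal.cx < size and 0 <= proposal.cy < size):
                continue
            if any(polygon_iou(proposal, other) > spec.overlap_level for other in placed_boxes):
                continue
            color = _panicle_color(spec.stage_preset, rng)
            mask = np.zeros((size, size), dtype=np.float32)
            for a, b in segs:
                mask = np.maximum(mask, _draw_capsule(img, a, b, width, color, rng))
            box = _mask_box(mask)
            placed_boxes.append(box)
            records.append(AnnotationRecord("panicle", box, 0, f"scene-{seed}"))
            break
        else:
            raise PlacementError(
                f"could not place object {obj + 1}/{n} under overlap_level="
                f"{spec.overlap_level}; lower the density or raise the overlap level"
            )
    return np.clip(img, 0, 255).astype(np.uint8), records


def generate_dataset(
    spec: SceneSpec,
    n_train: int,
    n_val: int,
    out_dir: str | Path,
    seed: int = 0,
) -> Dict:
    """Write a train/val scene dataset in the standard detection layout.

    Produces ``images/{train,val}/*.png``, matching YOLO-OBB label files
    under ``labels/{train,val}``, a ``data.yaml`` manifest naming splits and
    classes, and a ``provenance.json`` recording the spec and seed.
    Returns the manifest dict.
    """
    import yaml

    out = Path(out_dir)
    class_map = {"panicle": 0}
    ss = np.random.SeedSequence(seed)
    scene_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_train + n_val)]
    counts = {"train": n_train, "val": n_val}
    idx = 0
    for split, count in counts.items():
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
        for i in range(count):
            img, records = generate_scene(spec, scene_seeds[idx])
            stem = f"scene_{split}_{i:04d}"
            save_image(out / "images" / split / f"{stem}.png", img)
            lines = records_to_yolo_obb(records, spec.image_size, spec.image_size, class_map)
            (out / "labels" / split / f"{stem}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )
            idx += 1
    manifest = {
        "path": str(out),
        "train": "images/train",
        "val": "images/val",
        "nc": 1,
        "names": {0: "panicle"},
        "image_size": spec.image_size,
    }
    (out / "data.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    provenance = {"spec": dataclasses.asdict(spec), "seed": seed,
                  "n_train": n_train, "n_val": n_val}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return manifest
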