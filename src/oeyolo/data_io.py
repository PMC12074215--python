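"""Annotation parsing, format conversion, image tiling and OBB-consistent
augmentation.

The annotation pipeline mirrors the field workflow for oriented-box UAV
datasets: rolabelImg XML (center/size/angle per object) is converted to
DOTA text (eight vertex coordinates, class name, difficulty flag) and then
to normalized YOLO-OBB text (class index + eight coordinates in [0, 1]).
Large source frames are cropped into square tiles with annotations clipped,
re-fit as minimum-area rectangles and filtered by retained-area fraction.

Coordinates are continuous and 0-based over the half-open image domain
[0, W) x [0, H), with pixel (r, c) covering [c, c+1) x [r, r+1); this keeps
geometric image ops (flips, affine warps) and box transforms consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from lxml import etree

from oeyolo.geometry import (
    InvalidQuadError,
    OrientedBox,
    box_to_vertices,
    canonicalize_box,
    clip_polygon,
    min_area_rect,
    polygon_area,
    vertices_to_box,
)

__all__ = [
    "AnnotationRecord",
    "TileSet",
    "Tile",
    "AugmentationSpec",
    "AnnotationParseError",
    "ClassMapError",
    "parse_rolabelimg",
    "to_dota",
    "parse_dota",
    "dota_to_yolo_obb",
    "parse_yolo_obb",
    "records_to_yolo_obb",
    "tile_image",
    "augment",
    "load_image",
    "save_image",
]


class AnnotationParseError(ValueError):
    """Malformed or incomplete annotation input."""


class ClassMapError(KeyError):
    """A class name missing from the class map."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated object: class, oriented box, difficulty, provenance."""

    class_name: str
    box: OrientedBox
    difficulty: int = 0
    source: str = ""
    tile_offset: Tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class Tile:
    """One image tile: pixels, origin in the source frame, remapped boxes."""

    image: np.ndarray
    origin: Tuple[int, int]  # (x, y) of the tile's top-left in source pixels
    annotations: Tuple[AnnotationRecord, ...]


@dataclass(frozen=True)
class TileSet:
    tiles: Tuple[Tile, ...]
    tile_size: int
    grid: Tuple[int, int]  # (rows, cols)
    dropped: Tuple[AnnotationRecord, ...] = ()


# ---------------------------------------------------------------------------
# rolabelImg XML
# ---------------------------------------------------------------------------

def parse_rolabelimg(xml_text: str | bytes) -> List[AnnotationRecord]:
    """Parse rolabelImg XML into annotation records.

    Angles are the tool's convention, radians in [0, 2pi); boxes come back
    canonicalized.  Object order is preserved.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise AnnotationParseError(f"malformed XML: {exc}") from exc
    source = root.findtext("filename", default="")
    records: List[AnnotationRecord] = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        if name is None:
            raise AnnotationParseError("object element missing <name>")
        rb = obj.find("robndbox")
        if rb is None:
            raise AnnotationParseError(f"object {name!r} missing <robndbox>")
        values = {}
        for key in ("cx", "cy", "w", "h", "angle"):
            text = rb.findtext(key)
            if text is None:
                raise AnnotationParseError(f"robndbox of {name!r} missing <{key}>")
            try:
                values[key] = float(text)
            except ValueError as exc:
                raise AnnotationParseError(f"non-numeric <{key}> in {name!r}: {text!r}") from exc
        difficulty = int(obj.findtext("difficult", default="0"))
        box = canonicalize_box(
            OrientedBox(values["cx"], values["cy"], values["w"], values["h"], values["angle"])
        )
        records.append(AnnotationRecord(name, box, difficulty, source))
    return records


# ---------------------------------------------------------------------------
# DOTA text
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    """Format a coordinate with six decimals, trailing zeros trimmed but at
    least one decimal place kept (``80.0`` not ``80``)."""
    text = f"{value:.6f}".rstrip("0")
    if text.endswith("."):
        text += "0"
    return text


def to_dota(records: Sequence[AnnotationRecord]) -> List[str]:
    """Serialize records as DOTA lines: eight vertex coordinates, class name,
    difficulty flag."""
    lines = []
    for rec in records:
        verts = box_to_vertices(rec.box).reshape(-1)
        coords = " ".join(_fmt(v) for v in verts)
        lines.append(f"{coords} {rec.class_name} {rec.difficulty}")
    return lines


def parse_dota(lines: Iterable[str], source: str = "") -> List[AnnotationRecord]:
    """Parse DOTA lines back into records (boxes re-fit from vertices)."""
    records = []
    for ln, line in enumerate(lines, 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 10:
            raise AnnotationParseError(f"DOTA line {ln}: expected 10 fields, got {len(parts)}")
        try:
            coords = [float(p) for p in parts[:8]]
        except ValueError as exc:
            raise AnnotationParseError(f"DOTA line {ln}: non-numeric coordinate") from exc
        name, difficulty = parts[8], int(parts[9])
        box = vertices_to_box(np.array(coords).reshape(4, 2))
        records.append(AnnotationRecord(name, box, difficulty, source))
    return records


# ---------------------------------------------------------------------------
# YOLO-OBB text
# ---------------------------------------------------------------------------

def dota_to_yolo_obb(
    dota_lines: Iterable[str],
    image_w: int,
    image_h: int,
    class_map: Dict[str, int],
) -> List[str]:
    """Convert DOTA lines to YOLO-OBB lines: class index then eight vertex
    coordinates normalized to [0, 1] by image width/height (clamped)."""
    if image_w <= 0 or image_h <= 0:
        raise ValueError(f"image dimensions must be positive, got {image_w}x{image_h}")
    out = []
    for ln, line in enumerate(dota_lines, 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 10:
            raise AnnotationParseError(f"DOTA line {ln}: expected 10 fields, got {len(parts)}")
        name = parts[8]
        if name not in class_map:
            raise ClassMapError(f"class {name!r} not in class map")
        coords = np.array([float(p) for p in parts[:8]], dtype=float).reshape(4, 2)
        coords[:, 0] = np.clip(coords[:, 0] / image_w, 0.0, 1.0)
        coords[:, 1] = np.clip(coords[:, 1] / image_h, 0.0, 1.0)
        fields = " ".join(_fmt(v) for v in coords.reshape(-1))
        out.append(f"{class_map[name]} {fields}")
    return out


def records_to_yolo_obb(
    records: Sequence[AnnotationRecord],
    image_w: int,
    image_h: int,
    class_map: Dict[str, int],
) -> List[str]:
    """Records straight to YOLO-OBB text (via the DOTA representation)."""
    return dota_to_yolo_obb(to_dota(records), image_w, image_h, class_map)


def parse_yolo_obb(
    lines: Iterable[str],
    image_w: int,
    image_h: int,
    class_names: Sequence[str],
    source: str = "",
) -> List[AnnotationRecord]:
    """Parse YOLO-OBB lines back into records in pixel coordinates."""
    records = []
    for ln, line in enumerate(lines, 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 9:
            raise AnnotationParseError(f"YOLO-OBB line {ln}: expected 9 fields, got {len(parts)}")
        cls = int(parts[0])
        coords = np.array([float(p) for p in parts[1:]], dtype=float).reshape(4, 2)
        coords[:, 0] *= image_w
        coords[:, 1] *= image_h
        box = vertices_to_box(coords)
        records.append(AnnotationRecord(class_names[cls], box, 0, source))
    return records


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_image(
    image: np.ndarray,
    annotations: Sequence[AnnotationRecord],
    tile: int = 608,
    min_area_frac: float = 0.30,
) -> TileSet:
    """Crop an image into a grid of square tiles and remap annotations.

    The grid is ceil(H/tile) x ceil(W/tile); images not divisible by the
    tile size are reflection-padded on the bottom/right.  Each annotation's
    quad is clipped to every tile it touches and re-fit as the minimum-area
    rectangle of the clipped polygon; it is kept in a tile iff the retained
    area is at least ``min_area_frac`` of the original box area.  Boxes that
    survive in no tile are reported in ``TileSet.dropped``.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if not 0.0 <= min_area_frac <= 1.0:
        raise ValueError("min_area_frac must lie in [0, 1]")
    if tile <= 0:
        raise ValueError("tile size must be positive")
    h, w = img.shape[:2]
    rows = math.ceil(h / tile)
    cols = math.ceil(w / tile)
    pad_h, pad_w = rows * tile - h, cols * tile - w
    if pad_h or pad_w:
        pad_spec = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad_spec, mode="reflect")

    tiles: List[Tile] = []
    placed = [False] * len(annotations)
    for r in range(rows):
        for c in range(cols):
            x0, y0 = c * tile, r * tile
            tile_rect = np.array(
                [[x0, y0], [x0 + tile, y0], [x0 + tile, y0 + tile], [x0, y0 + tile]],
                dtype=float,
            )
            kept: List[AnnotationRecord] = []
            for ai, rec in enumerate(annotations):
                verts = box_to_vertices(rec.box)
                clipped = clip_polygon(verts, tile_rect)
                area = polygon_area(clipped)
                if area < min_area_frac * rec.box.area or len(clipped) < 3:
                    continue
                try:
                    local = min_area_rect(clipped - np.array([x0, y0], dtype=float))
                except InvalidQuadError:
                    continue
                kept.append(replace(rec, box=local, tile_offset=(x0, y0)))
                placed[ai] = True
            tiles.append(
                Tile(img[y0 : y0 + tile, x0 : x0 + tile].copy(), (x0, y0), tuple(kept))
            )
    dropped = tuple(rec for rec, ok in zip(annotations, placed) if not ok)
    return TileSet(tuple(tiles), tile, (rows, cols), dropped)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    """Enabled transforms and their parameter ranges.

    Geometric transforms move pixels and boxes identically; photometric
    transforms leave annotations untouched.
    """

    hflip_prob: float = 0.5
    scale_range: Tuple[float, float] = (0.8, 1.2)
    translate_frac: float = 0.10
    rotate_deg: float = 15.0
    contrast_range: Tuple[float, float] = (0.8, 1.2)
    blur_sigma_max: float = 1.5
    affine_prob: float = 0.5
    contrast_prob: float = 0.5
    blur_prob: float = 0.3


def _affine_boxes(
    records: Sequence[AnnotationRecord],
    matrix: np.ndarray,
    offset: np.ndarray,
    width: int,
    height: int,
) -> Tuple[List[AnnotationRecord], List[AnnotationRecord]]:
    kept, dropped = [], []
    for rec in records:
        verts = box_to_vertices(rec.box) @ matrix.T + offset
        box = min_area_rect(verts)
        if 0 <= box.cx < width and 0 <= box.cy < height:
            kept.append(replace(rec, box=box))
        else:
            dropped.append(rec)
    return kept, dropped


def augment(
    image: np.ndarray,
    annotations: Sequence[AnnotationRecord],
    spec: AugmentationSpec = AugmentationSpec(),
    seed: int = 0,
) -> Tuple[np.ndarray, List[AnnotationRecord]]:
    """Seeded augmentation of an image and its oriented-box annotations.

    Applies (in order, each with its own probability): horizontal flip,
    affine scale/translate/rotate about the image center, contrast gain and
    Gaussian blur.  Boxes whose transformed center leaves the frame are
    dropped.  Identical seeds produce identical outputs.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    img = np.asarray(image).astype(np.float32)
    h, w = img.shape[:2]
    records = list(annotations)

    if rng.random() < spec.hflip_prob:
        img = img[:, ::-1].copy()
        records = [
            replace(
                rec,
                box=canonicalize_box(
                    OrientedBox(w - rec.box.cx, rec.box.cy, rec.box.w, rec.box.h, -rec.box.theta)
                ),
            )
            for rec in records
        ]

    if rng.random() < spec.affine_prob:
        s = rng.uniform(*spec.scale_range)
        phi = math.radians(rng.uniform(-spec.rotate_deg, spec.rotate_deg))
        tx = rng.uniform(-spec.translate_frac, spec.translate_frac) * w
        ty = rng.uniform(-spec.translate_frac, spec.translate_frac) * h
        c, si = math.cos(phi), math.sin(phi)
        matrix = s * np.array([[c, -si], [si, c]])
        center = np.array([w / 2.0, h / 2.0])
        offset = center + np.array([tx, ty]) - matrix @ center
        # image resampling uses the inverse map (output pixel -> input pixel)
        inv = np.linalg.inv(matrix)
        inv_offset = -inv @ offset
        chans = [
            ndimage.affine_transform(
                img[..., ch] if img.ndim == 3 else img,
                _swap_xy(inv),
                offset=inv_offset[::-1],
                order=1,
                mode="constant",
                cval=0.0,
            )
            for ch in range(img.shape[2] if img.ndim == 3 else 1)
        ]
        img = np.stack(chans, axis=-1) if img.ndim == 3 else chans[0]
        records, _ = _affine_boxes(records, matrix, offset, w, h)

    if rng.random() < spec.contrast_prob:
        gain = rng.uniform(*spec.contrast_range)
        mean = img.mean()
        img = np.clip((img - mean) * gain + mean, 0, 255)

    if rng.random() < spec.blur_prob:
        sigma = rng.uniform(0.0, spec.blur_sigma_max)
        if sigma > 1e-3:
            if img.ndim == 3:
                img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
            else:
                img = ndimage.gaussian_filter(img, sigma=sigma)

    return img.astype(np.uint8), records


def _swap_xy(m: np.ndarray) -> np.ndarray:
    """Convert an (x, y) linear map to scipy's (row, col) convention."""
    return np.array([[m[1, 1], m[1, 0]], [m[0, 1], m[0, 0]]])


# ---------------------------------------------------------------------------
# image files
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as uint8 (H, W, 3)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path: str | Path, image: np.ndarray) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)
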