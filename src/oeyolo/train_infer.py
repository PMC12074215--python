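"""Target assignment, the ProbIoU detection loss, the training loop and
inference with rotated NMS.

Loss design
-----------
The box regression term replaces area-overlap losses with the probabilistic
IoU: for each positive location the penalty is ``1 - ProbIoU(pred, gt)``,
which is smooth in all five box parameters (center, sides, angle) and keeps
a useful gradient even when prediction and target do not overlap — the
property that matters for slender, arbitrarily oriented targets.  The
classification term is binary cross-entropy over every location of every
pyramid level (optionally positive-weighted to counter the extreme
background imbalance of dense small-object scenes).

Assignment
----------
:func:`assign_targets` scores candidate boxes against ground truth with the
exact polygon IoU and declares positives at IoU >= ``pos_thr`` (0.7 by
default), matched to the argmax ground truth.  For the anchor-free heads the
training loop uses a center-prior assigner instead: each ground-truth box
claims the grid cells (at the pyramid level matching its size) whose centers
fall inside the rotated rectangle, with the center cell as fallback; an
IoU-threshold rule over grid cells cannot produce positives for boxes much
more elongated than a cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from oeyolo import nn
from oeyolo.data_io import (
    AnnotationRecord,
    AugmentationSpec,
    augment,
    load_image,
    parse_yolo_obb,
)
from oeyolo.geometry import Detection, OrientedBox, canonicalize_box, polygon_iou, rotated_nms
from oeyolo.network import ModelConfig, OEYOLO, build_oe_yolo
from oeyolo.nn import Tensor

__all__ = [
    "TrainConfig",
    "Assignment",
    "assign_targets",
    "detection_loss",
    "train",
    "detect",
    "decode_outputs",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Detector training schedule and loss configuration.

    Defaults follow the reference protocol: 110 epochs, initial learning
    rate 0.01 with cosine annealing (floor lr0/100), SGD momentum 0.937,
    L2 weight decay 0.001, 608 px inputs.
    """

    epochs: int = 110
    initial_lr: float = 0.01
    min_lr: Optional[float] = None  # defaults to initial_lr / 100
    momentum: float = 0.937
    weight_decay: float = 0.001
    image_size: int = 608
    batch_size: int = 16
    seed: int = 0
    assignment_iou_pos: float = 0.7
    box_weight: float = 7.5
    cls_weight: float = 1.0
    cls_pos_weight: float = 1.0
    augmentation: Optional[AugmentationSpec] = field(default_factory=AugmentationSpec)
    val_interval: int = 1  # epochs between val mAP50 evaluations (0 = final only)
    val_conf_thr: float = 0.05  # low threshold for the PR sweep during validation
    conf_thr: float = 0.25
    nms_iou: float = 0.35
    gate_temperature: Tuple[float, float, int] = (30.0, 1.0, 10)  # start, end, epochs

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.image_size % 32:
            raise ValueError("image_size must be a multiple of 32")


@dataclass(frozen=True)
class Assignment:
    """Candidate labels: +1 positive (with matched gt index), 0 negative."""

    positive: np.ndarray  # bool (n_candidates,)
    matched_gt: np.ndarray  # int (n_candidates,), -1 for negatives


def assign_targets(
    candidates: Sequence[OrientedBox],
    gts: Sequence[OrientedBox],
    pos_thr: float = 0.7,
) -> Assignment:
    """IoU-threshold assignment: a candidate is positive iff its best exact
    polygon IoU over ground truths reaches ``pos_thr``; it is matched to the
    argmax ground truth (ties to the lower index)."""
    if not (0.0 < pos_thr <= 1.0):
        raise ValueError("pos_thr must lie in (0, 1]")
    n = len(candidates)
    positive = np.zeros(n, dtype=bool)
    matched = np.full(n, -1, dtype=int)
    if gts:
        for i, cand in enumerate(candidates):
            ious = np.array([polygon_iou(cand, gt) for gt in gts])
            best = int(ious.argmax())
            if ious[best] >= pos_thr:
                positive[i] = True
                matched[i] = best
    return Assignment(positive, matched)


# ---------------------------------------------------------------------------
# differentiable ProbIoU (mirrors geometry.prob_iou on tensors)
# ---------------------------------------------------------------------------

def _probiou_vec(pred: Dict[str, Tensor], gt: Dict[str, np.ndarray]) -> Tensor:
    """Vectorized ProbIoU between predicted boxes (autograd tensors of cx,
    cy, w, h, theta) and ground-truth boxes (numpy constants)."""
    c1, s1 = pred["theta"].cos(), pred["theta"].sin()
    w2_1 = pred["w"] * pred["w"] * (1.0 / 12.0)
    h2_1 = pred["h"] * pred["h"] * (1.0 / 12.0)
    a1 = w2_1 * c1 * c1 + h2_1 * s1 * s1
    b1 = w2_1 * s1 * s1 + h2_1 * c1 * c1
    c1x = (w2_1 - h2_1) * c1 * s1

    c2, s2 = np.cos(gt["theta"]), np.sin(gt["theta"])
    w2_2 = gt["w"] ** 2 / 12.0
    h2_2 = gt["h"] ** 2 / 12.0
    a2 = w2_2 * c2 * c2 + h2_2 * s2 * s2
    b2 = w2_2 * s2 * s2 + h2_2 * c2 * c2
    c2x = (w2_2 - h2_2) * c2 * s2

    am = (a1 + a2) * 0.5
    bm = (b1 + b2) * 0.5
    cm = (c1x + c2x) * 0.5
    det_m = (am * bm - cm * cm).clamp(1e-9, None)
    det1 = (a1 * b1 - c1x * c1x).clamp(1e-9, None)
    det2 = np.maximum(a2 * b2 - c2x * c2x, 1e-9)

    dx = pred["cx"] - gt["cx"]
    dy = pred["cy"] - gt["cy"]
    quad = (bm * dx * dx - cm * dx * dy * 2.0 + am * dy * dy) / det_m
    b_d = quad * 0.125 + (det_m / (det1 * det2) ** 0.5).log() * 0.5
    bc = (-b_d).exp().clamp(0.0, 1.0)
    hd = ((1.0 - bc).clamp(0.0, 1.0) + 1e-12).sqrt()
    return (1.0 - hd).clamp(0.0, 1.0)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _gather(map_t: Tensor, bi, yi, xi) -> Tensor:
    """Gather (C,) vectors at (image, row, col) locations -> (P, C)."""
    # transpose to NHWC then fancy-index rows
    t = map_t.transpose(0, 2, 3, 1)
    return t[(bi, yi, xi)]


def decode_positions(
    level_out: Tuple[Tensor, Tensor, Tensor],
    stride: int,
    reg_max: int,
    direct: bool,
    bi: np.ndarray,
    yi: np.ndarray,
    xi: np.ndarray,
) -> Dict[str, Tensor]:
    """Differentiably decode box parameters at selected grid locations.

    Distributional mode: four side distances (left/top/right/bottom in the
    box frame) are expectations of per-side softmax distributions over
    ``reg_max`` bins, scaled by the stride; the center is the grid center
    plus the rotated offset; width/height are the side-distance sums.
    Direct mode: bounded offsets via tanh and sizes via scaled sigmoids.
    """
    box_map, _, angle_map = level_out
    gx = (xi + 0.5) * stride
    gy = (yi + 0.5) * stride
    theta = (_gather(angle_map, bi, yi, xi)[:, 0].sigmoid() - 0.5) * math.pi
    ct, st = theta.cos(), theta.sin()
    raw = _gather(box_map, bi, yi, xi)  # (P, 4*reg_max) or (P, 4)
    if direct:
        off_x = raw[:, 0].tanh() * (4.0 * stride)
        off_y = raw[:, 1].tanh() * (4.0 * stride)
        w = raw[:, 2].sigmoid() * (16.0 * stride)
        h = raw[:, 3].sigmoid() * (16.0 * stride)
        cx = off_x * ct - off_y * st + gx
        cy = off_x * st + off_y * ct + gy
    else:
        p = raw.reshape(len(bi), 4, reg_max).softmax(axis=-1)
        bins = np.arange(reg_max, dtype=np.float32)
        d = (p * bins.reshape(1, 1, -1)).sum(axis=-1) * float(stride)  # (P, 4) l,t,r,b
        xf = (d[:, 2] - d[:, 0]) * 0.5
        yf = (d[:, 3] - d[:, 1]) * 0.5
        cx = xf * ct - yf * st + gx
        cy = xf * st + yf * ct + gy
        w = (d[:, 0] + d[:, 2]).clamp(1e-3, None)
        h = (d[:, 1] + d[:, 3]).clamp(1e-3, None)
        return {"cx": cx, "cy": cy, "w": w, "h": h, "theta": theta, "dist": d}
    return {"cx": cx, "cy": cy, "w": w, "h": h, "theta": theta}


def decode_outputs(
    outputs: Sequence[Tuple[Tensor, Tensor, Tensor]],
    strides: Sequence[int],
    reg_max: int,
    direct: bool,
    conf_thr: float,
) -> List[Detection]:
    """Decode one image's raw pyramid outputs into scored detections
    (no gradient; scores are sigmoid class probabilities)."""
    dets: List[Detection] = []
    for (box_map, cls_map, angle_map), stride in zip(outputs, strides):
        scores = 1.0 / (1.0 + np.exp(-cls_map.data[0]))  # (nc, H, W)
        best_cls = scores.argmax(axis=0)
        best_score = scores.max(axis=0)
        yi, xi = np.nonzero(best_score >= conf_thr)
        if len(yi) == 0:
            continue
        bi = np.zeros_like(yi)
        params = decode_positions(
            (box_map, cls_map, angle_map), stride, reg_max, direct, bi, yi, xi
        )
        for k in range(len(yi)):
            box = canonicalize_box(
                OrientedBox(
                    float(params["cx"].data[k]),
                    float(params["cy"].data[k]),
                    max(float(params["w"].data[k]), 1e-3),
                    max(float(params["h"].data[k]), 1e-3),
                    float(params["theta"].data[k]),
                )
            )
            dets.append(
                Detection(box, float(best_score[yi[k], xi[k]]), int(best_cls[yi[k], xi[k]]))
            )
    return dets


# ---------------------------------------------------------------------------
# training assignment (center prior over pyramid levels)
# ---------------------------------------------------------------------------

def _select_level(box: OrientedBox, strides: Sequence[int]) -> int:
    """Coarsest level whose cell size still fits inside the box's short
    side; level 0 when even the finest does not fit."""
    level = 0
    for i, s in enumerate(strides):
        if min(box.w, box.h) >= s:
            level = i
    return level


def build_center_assignment(
    gts_per_image: Sequence[Sequence[OrientedBox]],
    shapes: Sequence[Tuple[int, int]],
    strides: Sequence[int],
    center_shrink: float = 0.4,
) -> Tuple[List[Dict[str, np.ndarray]], List[np.ndarray]]:
    """Center-prior positive assignment for a batch.

    Cells become positive when their centers fall inside the ground-truth
    rectangle shrunk by ``center_shrink`` about its center (center sampling:
    cells near the ends of a slender box would have to regress extreme
    offsets and yield poorly localized duplicates).  Returns per level: dict
    of (bi, yi, xi, gt_flat_index) positive locations, and per level a
    {0,1} classification target map (N, H, W).  ``gt_flat_index`` indexes
    the concatenation of all images' ground truths.
    """
    n_images = len(gts_per_image)
    per_level = [
        {"bi": [], "yi": [], "xi": [], "gt": []} for _ in strides
    ]
    cls_targets = [np.zeros((n_images, h, w), dtype=np.float32) for h, w in shapes]
    gt_offset = 0
    for img_i, gts in enumerate(gts_per_image):
        claimed: List[Dict[Tuple[int, int], Tuple[float, int]]] = [
            {} for _ in strides
        ]
        for gi, gt in enumerate(gts):
            li = _select_level(gt, strides)
            s = strides[li]
            hh, ww = shapes[li]
            verts_r = max(gt.w, gt.h) / 2.0
            x_lo = max(int((gt.cx - verts_r) / s) - 1, 0)
            x_hi = min(int((gt.cx + verts_r) / s) + 1, ww - 1)
            y_lo = max(int((gt.cy - verts_r) / s) - 1, 0)
            y_hi = min(int((gt.cy + verts_r) / s) + 1, hh - 1)
            ct, st = math.cos(gt.theta), math.sin(gt.theta)
            found = False
            for yy in range(y_lo, y_hi + 1):
                cyp = (yy + 0.5) * s - gt.cy
                for xx in range(x_lo, x_hi + 1):
                    cxp = (xx + 0.5) * s - gt.cx
                    u = cxp * ct + cyp * st
                    v = -cxp * st + cyp * ct
                    if (
                        abs(u) <= gt.w / 2.0 * center_shrink
                        and abs(v) <= max(gt.h / 2.0 * center_shrink, s / 2.0)
                    ):
                        d2 = cxp * cxp + cyp * cyp
                        prev = claimed[li].get((yy, xx))
                        if prev is None or d2 < prev[0]:
                            claimed[li][(yy, xx)] = (d2, gt_offset + gi)
                        found = True
            if not found:
                hh0, ww0 = shapes[li]
                xx = min(max(int(gt.cx / s), 0), ww0 - 1)
                yy = min(max(int(gt.cy / s), 0), hh0 - 1)
                prev = claimed[li].get((yy, xx))
                if prev is None:
                    claimed[li][(yy, xx)] = (0.0, gt_offset + gi)
        for li in range(len(strides)):
            for (yy, xx), (_, gidx) in claimed[li].items():
                per_level[li]["bi"].append(img_i)
                per_level[li]["yi"].append(yy)
                per_level[li]["xi"].append(xx)
                per_level[li]["gt"].append(gidx)
                cls_targets[li][img_i, yy, xx] = 1.0
        gt_offset += len(gts)
    out = []
    for li in range(len(strides)):
        out.append({k: np.asarray(v, dtype=int) for k, v in per_level[li].items()})
    return out, cls_targets


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def detection_loss(
    outputs: Sequence[Tuple[Tensor, Tensor, Tensor]],
    assignment: Tuple[List[Dict[str, np.ndarray]], List[np.ndarray]],
    gts_flat: Sequence[OrientedBox],
    strides: Sequence[int],
    reg_max: int,
    direct: bool,
    box_weight: float = 7.5,
    cls_weight: float = 1.0,
    cls_pos_weight: float = 1.0,
    quality_targets: bool = True,
    dist_weight: float = 0.5,
) -> Tuple[Tensor, Tensor, Tensor]:
    """Composite detection loss: ``total = w_box * box + w_cls * cls``.

    box = mean over positives of (1 - ProbIoU(pred, matched gt)) plus, in
    distributional mode, ``dist_weight`` times an L1 penalty (in cell units)
    between the decoded side distances and the true cell-to-edge distances
    in the box frame.  The distance term supplies the major-axis length
    signal that the Gaussian overlap barely carries for slender boxes (the
    variance along the long side makes ProbIoU forgiving of length errors,
    so long objects would otherwise split into several shorter detections).
    cls = (optionally positive-weighted) binary cross-entropy over every
    location of every level, normalized by the positive count.  With
    ``quality_targets`` the positive targets are the detached ProbIoU of the
    current prediction rather than hard ones, so the confidence learns to
    rank localization quality — poorly aligned duplicate detections score
    low instead of competing with the best-aligned cell.
    """
    pos_per_level, cls_targets = assignment
    gt_cx = np.array([g.cx for g in gts_flat], dtype=np.float32)
    gt_cy = np.array([g.cy for g in gts_flat], dtype=np.float32)
    gt_w = np.array([g.w for g in gts_flat], dtype=np.float32)
    gt_h = np.array([g.h for g in gts_flat], dtype=np.float32)
    gt_t = np.array([g.theta for g in gts_flat], dtype=np.float32)

    probiou_sum: Optional[Tensor] = None
    n_pos = 0
    cls_sum: Optional[Tensor] = None
    n_loc = 0
    for li, ((box_map, cls_map, angle_map), stride) in enumerate(zip(outputs, strides)):
        pos = pos_per_level[li]
        target = cls_targets[li]
        if len(pos["bi"]):
            pred = decode_positions(
                (box_map, cls_map, angle_map), stride, reg_max, direct,
                pos["bi"], pos["yi"], pos["xi"],
            )
            gsel = pos["gt"]
            gt = {
                "cx": gt_cx[gsel], "cy": gt_cy[gsel],
                "w": gt_w[gsel], "h": gt_h[gsel], "theta": gt_t[gsel],
            }
            piou = _probiou_vec(pred, gt)
            term = (1.0 - piou).sum()
            if not direct and dist_weight > 0:
                # true cell-to-edge distances in the ground-truth box frame
                gxc = (pos["xi"] + 0.5) * stride - gt["cx"]
                gyc = (pos["yi"] + 0.5) * stride - gt["cy"]
                ctg, stg = np.cos(gt["theta"]), np.sin(gt["theta"])
                u = gxc * ctg + gyc * stg
                v = -gxc * stg + gyc * ctg
                limit = (reg_max - 1) * stride
                targets = np.clip(
                    np.stack([gt["w"] / 2 + u, gt["h"] / 2 + v,
                              gt["w"] / 2 - u, gt["h"] / 2 - v], axis=1),
                    0.0, limit,
                ).astype(np.float32)
                diff = pred["dist"] - targets
                abs_diff = (diff * diff + 1e-6).sqrt()  # smooth |.|
                term = term + abs_diff.sum(axis=1).sum() * (dist_weight / stride)
            probiou_sum = term if probiou_sum is None else probiou_sum + term
            n_pos += len(gsel)
            if quality_targets:
                target = target.copy()
                target[pos["bi"], pos["yi"], pos["xi"]] = np.maximum(
                    piou.data.astype(np.float32), 0.02
                )
        # classification over all locations of this level
        target = target[:, None]  # (N,1,H,W) single-class
        p = cls_map.sigmoid().clamp(1e-7, 1.0 - 1e-7)
        bce = -(
            target * p.log() * cls_pos_weight + (1.0 - target) * (1.0 - p).log()
        ).sum()
        cls_sum = bce if cls_sum is None else cls_sum + bce
        n_loc += int(np.prod(cls_map.shape))

    box_term = (
        probiou_sum * (1.0 / n_pos) if n_pos else Tensor(np.zeros(()))
    )
    # normalize the summed BCE by the positive count (the detection-loss
    # convention that keeps the foreground gradient independent of how many
    # background locations the pyramid happens to contain)
    cls_term = cls_sum * (1.0 / max(n_pos, 1))
    total = box_term * box_weight + cls_term * cls_weight
    return total, box_term, cls_term


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------

def load_dataset(
    manifest_path: str | Path, split: str = "train", image_size: Optional[int] = None
) -> List[Tuple[np.ndarray, List[OrientedBox]]]:
    """Load (image, gt boxes) pairs from a dataset manifest, optionally
    rescaled to a square training resolution."""
    import yaml

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    root = Path(manifest.get("path", manifest_path.parent))
    if not root.is_absolute():
        root = manifest_path.parent / root
    img_dir = root / manifest[split]
    label_dir = root / manifest[split].replace("images", "labels")
    names = [manifest["names"][k] for k in sorted(manifest["names"])]
    samples = []
    for img_path in sorted(img_dir.iterdir()):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        img = load_image(img_path)
        h, w = img.shape[:2]
        label_path = label_dir / (img_path.stem + ".txt")
        lines = label_path.read_text().splitlines() if label_path.exists() else []
        recs = parse_yolo_obb(lines, w, h, names, source=img_path.name)
        boxes = [r.box for r in recs]
        if image_size is not None and (h, w) != (image_size, image_size):
            from PIL import Image

            scale_x, scale_y = image_size / w, image_size / h
            img = np.asarray(
                Image.fromarray(img).resize((image_size, image_size), Image.BILINEAR)
            )
            boxes = [_rescale_box(b, scale_x, scale_y) for b in boxes]
        samples.append((img, boxes))
    if not samples:
        raise ValueError(f"no images found under {img_dir}")
    return samples


def _rescale_box(box: OrientedBox, sx: float, sy: float) -> OrientedBox:
    """Rescale a rotated box; exact for uniform scaling, min-area re-fit
    otherwise."""
    if abs(sx - sy) < 1e-9:
        return OrientedBox(box.cx * sx, box.cy * sy, box.w * sx, box.h * sx, box.theta)
    from oeyolo.geometry import box_to_vertices, min_area_rect

    verts = box_to_vertices(box) * np.array([sx, sy])
    return min_area_rect(verts)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(
    model: OEYOLO,
    dataset: str | Path | Sequence,
    cfg: TrainConfig,
    val_dataset: Optional[Sequence] = None,
) -> Tuple[OEYOLO, List[Dict]]:
    """Train the detector with SGD + momentum and cosine-annealed lr.

    ``dataset`` is a manifest path (data layout with train/val splits) or a
    pre-loaded list of (image, boxes) pairs.  Returns the trained model and
    a per-epoch metrics log (losses, lr, and val mAP50 at the configured
    interval).  Raises on an empty dataset and aborts on non-finite loss.
    """
    from oeyolo.evaluation import mean_ap

    if isinstance(dataset, (str, Path)):
        train_samples = load_dataset(dataset, "train", cfg.image_size)
        if val_dataset is None:
            try:
                val_dataset = load_dataset(dataset, "val", cfg.image_size)
            except (KeyError, ValueError, FileNotFoundError):
                val_dataset = None
    else:
        train_samples = list(dataset)
    if not train_samples:
        raise ValueError("empty training dataset")

    rng = np.random.default_rng(cfg.seed)
    nn.manual_seed(cfg.seed + 1)  # stochastic depth draws during training
    params = model.parameters()
    opt = nn.SGD(params, lr=cfg.initial_lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    strides = model.strides
    reg_max = model.cfg.reg_max
    direct = model.cfg.box_regression == "direct"
    t_start, t_end, t_epochs = cfg.gate_temperature

    log: List[Dict] = []
    for epoch in range(cfg.epochs):
        lr = nn.cosine_lr(cfg.initial_lr, epoch, cfg.epochs, cfg.min_lr)
        opt.lr = lr
        frac = min(epoch / max(t_epochs - 1, 1), 1.0) if t_epochs > 1 else 1.0
        model.set_gate_temperature(t_start + (t_end - t_start) * frac)
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_tot = epoch_box = epoch_cls = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            images, gts_per_image = [], []
            for bi_i, si in enumerate(batch_idx):
                img, boxes = train_samples[si]
                if cfg.augmentation is not None:
                    recs = [AnnotationRecord("obj", b) for b in boxes]
                    aug_seed = int((cfg.seed * 1000003 + epoch * 9973 + si) % (2**31))
                    img, recs = augment(img, recs, cfg.augmentation, aug_seed)
                    boxes = [r.box for r in recs]
                images.append(img.astype(np.float32) / 255.0)
                gts_per_image.append(boxes)
            x = Tensor(np.stack(images).transpose(0, 3, 1, 2))
            outputs = model(x)
            shapes = [(o[0].shape[2], o[0].shape[3]) for o in outputs]
            assignment = build_center_assignment(gts_per_image, shapes, strides)
            gts_flat = [b for boxes in gts_per_image for b in boxes]
            total, box_t, cls_t = detection_loss(
                outputs, assignment, gts_flat, strides, reg_max, direct,
                cfg.box_weight, cfg.cls_weight, cfg.cls_pos_weight,
            )
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"box={float(box_t.data)}, cls={float(cls_t.data)}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_tot += float(total.data)
            epoch_box += float(box_t.data)
            epoch_cls += float(cls_t.data)
            n_batches += 1
        record = {
            "epoch": epoch,
            "lr": lr,
            "loss": epoch_tot / n_batches,
            "box_loss": epoch_box / n_batches,
            "cls_loss": epoch_cls / n_batches,
        }
        evaluate_now = (
            val_dataset is not None
            and (
                (cfg.val_interval and (epoch + 1) % cfg.val_interval == 0)
                or epoch == cfg.epochs - 1
            )
        )
        if evaluate_now:
            dets, gts = [], []
            for img, boxes in val_dataset:
                dets.append(detect(model, img, cfg.val_conf_thr, cfg.nms_iou))
                gts.append(boxes)
            map50, map5095, _ = mean_ap(dets, gts)
            record["val_map50"] = map50
            record["val_map50_95"] = map5095
        log.append(record)
    return model, log


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def detect(
    model: OEYOLO,
    image: np.ndarray,
    conf_thr: float = 0.25,
    nms_iou: float = 0.35,
    image_size: Optional[int] = None,
    pre_nms_topk: int = 800,
    max_det: int = 300,
) -> List[Detection]:
    """Run the detector on one RGB image and return NMS-filtered detections
    in source-image pixel coordinates.

    The image is letterboxed (uniform scale, bottom/right padding) to a
    square multiple of 32 (``image_size`` when given, else the padded source
    size).  Images smaller than 32 px on a side are rejected.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if h < 32 or w < 32:
        raise ValueError(f"image too small for the detector: {w}x{h}")
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    if image_size is not None:
        scale = image_size / max(h, w)
        if abs(scale - 1.0) > 1e-9:
            from PIL import Image

            img = np.asarray(
                Image.fromarray(img.astype(np.uint8)).resize(
                    (max(round(w * scale), 1), max(round(h * scale), 1)), Image.BILINEAR
                )
            )
    else:
        scale = 1.0
    hh, ww = img.shape[:2]
    target = image_size if image_size is not None else 32 * math.ceil(max(hh, ww) / 32)
    pad_h, pad_w = target - hh, target - ww
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w), (0, 0)), mode="constant")

    was_training = model.training
    model.eval()
    x = Tensor(img.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    outputs = model(x)
    if was_training:
        model.train()
    dets = decode_outputs(
        outputs, model.strides, model.cfg.reg_max,
        model.cfg.box_regression == "direct", conf_thr,
    )
    # bound the NMS workload: keep the highest-scoring candidates only
    if len(dets) > pre_nms_topk:
        dets = sorted(dets, key=lambda d: -d.score)[:pre_nms_topk]
    dets = rotated_nms(dets, nms_iou)[:max_det]
    if scale != 1.0:
        inv = 1.0 / scale
        dets = [
            Detection(
                OrientedBox(d.box.cx * inv, d.box.cy * inv, d.box.w * inv,
                            d.box.h * inv, d.box.theta),
                d.score, d.class_id,
            )
            for d in dets
        ]
    return dets


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: OEYOLO, path: str | Path) -> None:
    """Serialize weights (.npz) with a JSON sidecar of the model config."""
    import dataclasses

    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg = dataclasses.asdict(model.cfg)
    cfg["backbone"]["stages"] = [list(s) for s in
                                 (dataclasses.astuple(st) for st in model.cfg.backbone.stages)]
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> OEYOLO:
    from oeyolo.network import BackboneSpec, StageSpec

    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    stages = tuple(StageSpec(*s) for s in cfg_raw["backbone"].pop("stages"))
    backbone = BackboneSpec(stages=stages, **cfg_raw.pop("backbone"))
    for key in ("tap_stages", "head_dconv", "neck_channels", "gate_temperature"):
        if key in cfg_raw and isinstance(cfg_raw[key], list):
            cfg_raw[key] = tuple(cfg_raw[key])
    cfg = ModelConfig(backbone=backbone, **cfg_raw)
    model = build_oe_yolo(cfg)
    state = dict(np.load(path if path.suffix == ".npz" else str(path) + ".npz"))
    model.load_state_dict(state)
    return model
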