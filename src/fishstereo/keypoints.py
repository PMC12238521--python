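"""Nine-keypoint fish schema, COCO-dialect annotation I/O and evaluation.

The fish is described by nine anatomical landmarks:

``mouth, eye, dorsal_fin1, dorsal_fin2, tail_fin1, tail_fin2, anal_fin,
top_fin, pelvic_fin``

where ``dorsal_fin1``/``dorsal_fin2`` are the anterior/posterior ends of the
dorsal fin and ``tail_fin1``/``tail_fin2`` the top/bottom of the tail fin.
Each landmark carries pixel coordinates (u, v) and a binary visibility flag.
Annotations travel in a COCO-style JSON dialect (flat 27-element keypoint
arrays, ``bbox = [x, y, w, h]``); the reader also accepts the standard COCO
three-state visibility, mapping 2 (visible) to 1.

Evaluation utilities: NME (mean keypoint error normalised by the bounding-box
diagonal) and AP over a sweep of IoU thresholds with greedy matching and
all-point precision-recall integration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

__all__ = [
    "KEYPOINT_NAMES",
    "SKELETON",
    "FishKeypoints",
    "Annotation",
    "ImageInfo",
    "AnnotationSet",
    "read_annotations",
    "write_annotations",
    "nme",
    "bbox_diagonal",
    "bbox_iou",
    "keypoints_bbox",
    "evaluate_detection",
]

KEYPOINT_NAMES: tuple[str, ...] = (
    "mouth",
    "eye",
    "dorsal_fin1",
    "dorsal_fin2",
    "tail_fin1",
    "tail_fin2",
    "anal_fin",
    "top_fin",
    "pelvic_fin",
)

#: 1-based index pairs tracing the fish outline, COCO-style.
SKELETON: tuple[tuple[int, int], ...] = (
    (1, 2),
    (2, 3),
    (3, 4),
    (4, 8),
    (8, 5),
    (5, 6),
    (6, 7),
    (7, 9),
    (9, 1),
)

N_KEYPOINTS = len(KEYPOINT_NAMES)


@dataclass
class FishKeypoints:
    """The 9 landmark positions of one fish in one image.

    Attributes
    ----------
    xy
        ``(9, 2)`` float array of (u, v) pixel coordinates, ordered as
        :data:`KEYPOINT_NAMES`.
    visibility
        ``(9,)`` int array with entries in {0, 1}.
    bbox
        Optional (x, y, w, h) pixel bounding box of the fish.
    """

    xy: np.ndarray
    visibility: np.ndarray
    bbox: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        vis = np.asarray(self.visibility, dtype=int)
        if xy.shape != (N_KEYPOINTS, 2):
            raise SchemaError(f"expected {N_KEYPOINTS} keypoints, got shape {xy.shape}")
        if vis.shape != (N_KEYPOINTS,) or not np.all(np.isin(vis, (0, 1))):
            raise SchemaError("visibility must be 9 flags in {0, 1}")
        self.xy = xy
        self.visibility = vis
        if self.bbox is not None:
            self.bbox = tuple(float(v) for v in self.bbox)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.xy[KEYPOINT_NAMES.index(name)]

    def is_visible(self, name: str) -> bool:
        return bool(self.visibility[KEYPOINT_NAMES.index(name)])

    def to_flat(self) -> list[float]:
        """Flat COCO keypoint array [x1, y1, v1, ..., x9, y9, v9]."""
        out: list[float] = []
        for (u, v), vis in zip(self.xy, self.visibility):
            out.extend([float(u), float(v), int(vis)])
        return out

    @classmethod
    def from_flat(
        cls, flat: list[float], bbox: tuple[float, float, float, float] | None = None
    ) -> "FishKeypoints":
        if len(flat) != 3 * N_KEYPOINTS:
            raise SchemaError(
                f"expected {3 * N_KEYPOINTS} keypoint values, got {len(flat)}"
            )
        arr = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
        vis = arr[:, 2].astype(int)
        if not np.all(np.isin(vis, (0, 1, 2))):
            raise SchemaError("keypoint visibility flags must be in {0, 1, 2}")
        vis = np.where(vis == 2, 1, vis)  # COCO 2 (labeled+visible) -> 1
        return cls(xy=arr[:, :2], visibility=vis, bbox=bbox)


@dataclass
class ImageInfo:
    file_name: str
    width: int
    height: int


@dataclass
class Annotation:
    image_id: int
    fish: FishKeypoints


@dataclass
class AnnotationSet:
    """In-memory COCO-dialect annotation file: images, annotations, one
    fish category."""

    images: dict[int, ImageInfo] = field(default_factory=dict)
    annotations: dict[int, Annotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ann_id, ann in self.annotations.items():
            if ann.image_id not in self.images:
                raise SchemaError(
                    f"annotation id={ann_id} references unknown image_id={ann.image_id}"
                )


def _category_record() -> dict:
    return {
        "id": 1,
        "name": "fish",
        "supercategory": "animal",
        "keypoints": list(KEYPOINT_NAMES),
        "skeleton": [list(pair) for pair in SKELETON],
    }


def read_annotations(path) -> AnnotationSet:
    """Read a COCO-dialect keypoint JSON file.

    Raises :class:`SchemaError` naming the offending record on malformed
    input (wrong keypoint count, bad visibility flag, dangling image_id).
    """
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("images", "annotations"):
        if key not in raw:
            raise SchemaError(f"missing top-level '{key}' array")
    images: dict[int, ImageInfo] = {}
    for rec in raw["images"]:
        try:
            images[int(rec["id"])] = ImageInfo(
                file_name=rec.get("file_name", ""),
                width=int(rec.get("width", 0)),
                height=int(rec.get("height", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed image record {rec!r}") from exc
    annotations: dict[int, Annotation] = {}
    for rec in raw["annotations"]:
        ann_id = rec.get("id")
        try:
            bbox = tuple(rec["bbox"]) if "bbox" in rec else None
            fish = FishKeypoints.from_flat(rec["keypoints"], bbox=bbox)
        except SchemaError as exc:
            raise SchemaError(f"annotation id={ann_id}: {exc}") from exc
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed annotation record id={ann_id}") from exc
        annotations[int(ann_id)] = Annotation(image_id=int(rec["image_id"]), fish=fish)
    return AnnotationSet(images=images, annotations=annotations)


def write_annotations(aset: AnnotationSet, path) -> None:
    """Write an :class:`AnnotationSet` as COCO-dialect JSON ({0,1} visibility).

    ``write(read(x))`` is lossless on the retained fields.
    """
    raw = {
        "images": [
            {
                "id": img_id,
                "file_name": info.file_name,
                "width": info.width,
                "height": info.height,
            }
            for img_id, info in sorted(aset.images.items())
        ],
        "annotations": [
            {
                "id": ann_id,
                "image_id": ann.image_id,
                "category_id": 1,
                "keypoints": ann.fish.to_flat(),
                "num_keypoints": int(np.sum(ann.fish.visibility)),
                **({"bbox": list(ann.fish.bbox)} if ann.fish.bbox else {}),
            }
            for ann_id, ann in sorted(aset.annotations.items())
        ],
        "categories": [_category_record()],
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def bbox_diagonal(bbox: tuple[float, float, float, float]) -> float:
    """Diagonal length (px) of an (x, y, w, h) box — the NME normaliser."""
    return float(np.hypot(bbox[2], bbox[3]))


def nme(truth: FishKeypoints, pred: FishKeypoints, normalizer: float) -> float:
    """Normalised mean error over jointly visible keypoints.

    Mean Euclidean pixel distance between matching keypoints divided by
    *normalizer* (the fish bounding-box diagonal).  Requires a positive
    normaliser and at least one jointly visible keypoint.
    """
    if not normalizer > 0:
        raise ValueError("NME normalizer must be > 0")
    both = (truth.visibility == 1) & (pred.visibility == 1)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no jointly visible keypoints to evaluate")
    dists = np.linalg.norm(truth.xy[both] - pred.xy[both], axis=1)
    return float(dists.mean() / normalizer)


def bbox_iou(a, b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def keypoints_bbox(kps: FishKeypoints) -> tuple[float, float, float, float]:
    """Tight (x, y, w, h) box around the visible keypoints."""
    pts = kps.xy[kps.visibility == 1]
    if len(pts) == 0:
        raise ValueError("no visible keypoints")
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    return (float(x0), float(y0), float(x1 - x0), float(y1 - y0))


def _ap_at_threshold(preds, truths, thr: float) -> float | None:
    """AP for one IoU threshold.  *preds*: image_id -> [(bbox, score)];
    *truths*: image_id -> [bbox]."""
    n_truth = sum(len(v) for v in truths.values())
    if n_truth == 0:
        return None
    # flatten and sort by score desc; ties keep insertion order (lowest index)
    flat = [
        (img_id, bbox, float(score))
        for img_id, lst in preds.items()
        for bbox, score in lst
    ]
    order = sorted(range(len(flat)), key=lambda i: -flat[i][2])
    matched: dict[int, set[int]] = {img_id: set() for img_id in truths}
    tp = np.zeros(len(flat))
    for rank, i in enumerate(order):
        img_id, bbox, _ = flat[i]
        gts = truths.get(img_id, [])
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if j in matched.get(img_id, set()):
                continue
            iou = bbox_iou(bbox, gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= thr:
            matched.setdefault(img_id, set()).add(best_j)
            tp[rank] = 1.0
    if len(flat) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.arange(1, len(flat) + 1)
    # all-point interpolation: integrate the precision envelope over recall
    mrec = np.concatenate([[0.0], recall, [recall[-1]]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def evaluate_detection(
    preds: dict[int, list[tuple[tuple, float]]],
    truths: dict[int, list[tuple]],
    iou_thresholds=tuple(np.round(np.arange(0.50, 0.96, 0.05), 2)),
) -> dict:
    """AP over a sweep of IoU thresholds with greedy box matching.

    Parameters
    ----------
    preds
        image_id -> list of ((x, y, w, h), score) detections.
    truths
        image_id -> list of (x, y, w, h) ground-truth boxes.
    iou_thresholds
        Thresholds in (0, 1]; default the COCO sweep 0.50:0.05:0.95.

    Returns
    -------
    dict with ``per_threshold`` (threshold -> AP, None when no ground truth)
    and ``mean_ap`` (mean over thresholds, None if undefined).
    """
    per = {float(t): _ap_at_threshold(preds, truths, float(t)) for t in iou_thresholds}
    vals = [v for v in per.values() if v is not None]
    return {
        "per_threshold": per,
        "mean_ap": float(np.mean(vals)) if vals else None,
    }
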