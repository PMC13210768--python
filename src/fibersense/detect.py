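"""Morphological fiber detection, counting criteria and evaluation harness.

Candidates are segmented from a composite image by background subtraction
and thresholding, measured on their medial-axis skeleton, and classified
against the standard fiber-counting criteria: length > 5 µm, width < 3 µm,
aspect ratio > 3:1, all strict, with aggregates (multi-branch skeletons)
excluded. Each candidate carries a confidence score in [0, 1]; counted
fibers must also clear a confidence threshold (default 0.32).

The detector is a deterministic, classical stand-in exposing the same
counting interface as the instrument's learned detector; no numeric
equivalence with a trained model is implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .edf import CompositeImage
from .errors import InputError, ParameterError
from .synth import SceneSpec, TruthLabel

__all__ = [
    "CountingCriteria",
    "DetectorConfig",
    "ComponentMetrics",
    "DetectedFiber",
    "DetectionMetrics",
    "MatchResult",
    "segment",
    "measure_component",
    "classify_fiber",
    "confidence_score",
    "detect_fibers",
    "field_report",
    "match_detections",
    "detection_metrics",
    "background_flag",
    "summarize_dataset",
    "split_dataset",
]

# Vossepoel–Smeulders step weights: unbiased digital length estimation on
# 8-connected paths (orthogonal / diagonal steps).
_W_ORTHO = 0.980
_W_DIAG = 1.406


@dataclass
class CountingCriteria:
    """The morphological counting rule for a countable fiber.

    All three inequalities are strict: length > L_min, width < W_max,
    aspect ratio > AR_min. Aggregated (entangled/crossing) fibers are
    excluded when ``exclude_aggregates`` is set.
    """

    L_min: float = 5.0
    W_max: float = 3.0
    AR_min: float = 3.0
    exclude_aggregates: bool = True

    def __post_init__(self) -> None:
        if self.L_min <= 0 or self.W_max <= 0:
            raise ParameterError("criteria lengths must be positive")
        if self.AR_min <= 1:
            raise ParameterError("AR_min must exceed 1")


@dataclass
class DetectorConfig:
    """Tunables of the classical detector."""

    threshold_method: str = "sigma"  # 'sigma' | 'otsu' | 'fixed'
    threshold_value: float | None = None  # used when threshold_method == 'fixed'
    sigma_k: float = 6.0  # k of the robust k-sigma threshold
    min_object_px: int = 10
    spur_prune_um: float = 2.0
    confidence_threshold: float = 0.32
    pixel_size: float = 0.33
    bg_window_um: float = 10.0  # scale of the grey-opening background estimate

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ParameterError("confidence_threshold must lie in [0, 1]")
        if self.threshold_method not in ("sigma", "otsu", "fixed"):
            raise ParameterError("threshold_method must be 'sigma', 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ParameterError("fixed thresholding requires threshold_value")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")


@dataclass
class ComponentMetrics:
    """Skeleton-based morphometry of one segmented component."""

    skeleton_length: float  # µm, longest geodesic path + endpoint correction
    width: float  # µm, from the medial-axis distance transform
    aspect_ratio: float
    n_skeleton_endpoints: int


@dataclass
class DetectedFiber:
    """One fiber candidate with measurements, confidence and verdict."""

    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) pixels, half-open
    centroid_um: tuple[float, float]
    skeleton_length: float
    width: float
    aspect_ratio: float
    confidence: float
    status: str  # 'countable' | 'rejected'
    reject_reason: str  # 'none' | 'too_short' | 'too_thick' | 'low_AR' | 'aggregate' | 'low_confidence'
    n_skeleton_endpoints: int = 2
    label: int = 0


@dataclass
class DetectionMetrics:
    """Confusion counts and derived rates; undefined ratios are None."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f_score: float | None
    accuracy: float | None


@dataclass
class MatchResult:
    """One-to-one pairing of countable detections with countable truths."""

    tp: int
    fp: int
    fn: int
    tn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (det idx, truth idx)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _as_raster(image) -> tuple[np.ndarray, float | None]:
    if isinstance(image, CompositeImage):
        return np.asarray(image.raster, dtype=np.float64), image.pixel_size
    return np.asarray(image, dtype=np.float64), None


def subtract_background(raster: np.ndarray, window_px: int) -> np.ndarray:
    """Remove smooth background by grey opening + smoothing (rolling-ball style)."""
    window_px = max(3, int(window_px))
    opened = ndi.grey_opening(raster, size=(window_px, window_px))
    bg = ndi.gaussian_filter(opened, window_px / 2.0)
    return np.clip(raster - bg, 0.0, None)


def _noise_sigma(residual: np.ndarray) -> float:
    """Robust noise scale of the background-subtracted image (MAD-based)."""
    med = np.median(residual)
    return float(1.4826 * np.median(np.abs(residual - med)))


def segment(image, config: DetectorConfig) -> np.ndarray:
    """Segment bright objects into a labelled component map.

    Background is removed by grey opening at ``bg_window_um``. The residual
    is thresholded: ``sigma`` (default) places the threshold a robust
    k-sigma above the residual median, which is stable for sparse bright
    objects on a dominant background; ``otsu`` uses Otsu's rule floored at
    that noise level; ``fixed`` uses a user value. Components smaller than
    ``min_object_px`` are discarded. Deterministic; an all-constant image
    yields an empty label map.
    """
    raster, px = _as_raster(image)
    if raster.size == 0:
        raise InputError("empty image")
    px = px or config.pixel_size
    sub = subtract_background(raster, int(round(config.bg_window_um / px)))
    if not np.any(sub > 0):
        return np.zeros(raster.shape, dtype=np.int32)
    if config.threshold_method == "fixed":
        thr = float(config.threshold_value)
    else:
        floor = float(np.median(sub) + config.sigma_k * _noise_sigma(sub))
        if config.threshold_method == "sigma":
            thr = floor
        else:
            try:
                thr = max(float(threshold_otsu(sub)), floor)
            except ValueError:  # constant image
                return np.zeros(raster.shape, dtype=np.int32)
    mask = sub > thr
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= config.min_object_px)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton with length-calibrated weights."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pixels)
    for r, c in pixels:
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (r + dr, c + dc)
            if nb in pixels:
                g.add_edge((r, c), nb, weight=_W_DIAG if dr and dc else _W_ORTHO)
    return g


def _prune_spurs(g: nx.Graph, max_len: float) -> nx.Graph:
    """Iteratively remove side branches shorter than ``max_len`` (pixels).

    A branch is the path from an endpoint to the nearest junction
    (degree >= 3 node); a skeleton that is a single open path is left
    untouched so genuine fibers are never shortened.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        junctions = {n for n in g if g.degree(n) >= 3}
        if not junctions:
            break
        for tip in [n for n in g if g.degree(n) == 1]:
            if tip not in g:
                continue
            path = [tip]
            length = 0.0
            node = tip
            prev = None
            while True:
                nbrs = [n for n in g.neighbors(node) if n != prev]
                if node in junctions or not nbrs:
                    break
                nxt = nbrs[0]
                length += g[node][nxt]["weight"]
                prev, node = node, nxt
                path.append(node)
            if node in junctions and length < max_len:
                g.remove_nodes_from(path[:-1])
                changed = True
    return g


def _geodesic_diameter(g: nx.Graph) -> float:
    """Longest shortest path (pixels) via a double sweep; exact on trees."""
    if g.number_of_nodes() <= 1:
        return 0.0
    start = next(iter(g.nodes))
    dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
    far = max(dist, key=dist.get)
    dist2 = nx.single_source_dijkstra_path_length(g, far, weight="weight")
    return float(max(dist2.values()))


def measure_component(
    mask: np.ndarray, pixel_size: float, spur_prune_um: float = 2.0
) -> ComponentMetrics:
    """Skeleton length, width and endpoint count of one component mask.

    Length is the longest geodesic path through the pruned skeleton plus a
    one-width endpoint correction (the skeleton retracts by about half the
    width at each end). Width is twice the median medial-axis half-width
    from the Euclidean distance transform, measured from the object
    boundary rather than between pixel centres (half-pixel correction).
    Endpoints are counted after pruning spurs shorter than
    ``spur_prune_um``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InputError("empty component mask")
    # One-pixel background border so the distance transform and skeleton
    # are correct for masks cropped tightly to the component.
    mask = np.pad(mask, 1)
    edt = ndi.distance_transform_edt(mask)
    skel = skeletonize(mask)
    if not skel.any():  # degenerate tiny mask
        side = math.sqrt(mask.sum()) * pixel_size
        return ComponentMetrics(side, side, 1.0, 0)
    g = _skeleton_graph(skel)
    if len(g) > 1:
        g = _prune_spurs(g, spur_prune_um / pixel_size)
    med_half = float(np.median(edt[tuple(np.array(list(g.nodes)).T)]))
    width = max(2.0 * med_half - 1.0, 1.0) * pixel_size
    diam_px = _geodesic_diameter(g)
    length = diam_px * pixel_size + width
    n_end = sum(1 for n in g if g.degree(n) <= 1)
    return ComponentMetrics(
        skeleton_length=length,
        width=width,
        aspect_ratio=length / width,
        n_skeleton_endpoints=n_end,
    )


# ---------------------------------------------------------------------------
# Classification and confidence
# ---------------------------------------------------------------------------


def classify_fiber(metrics: ComponentMetrics, criteria: CountingCriteria) -> tuple[str, str]:
    """Apply the counting criteria; first failing rule gives the reason.

    Rule order: length, width, aspect ratio, aggregate. Aggregates are
    components whose pruned skeleton has more than two endpoints.
    """
    if not metrics.skeleton_length > criteria.L_min:
        return "rejected", "too_short"
    if not metrics.width < criteria.W_max:
        return "rejected", "too_thick"
    if not metrics.aspect_ratio > criteria.AR_min:
        return "rejected", "low_AR"
    if criteria.exclude_aggregates and metrics.n_skeleton_endpoints > 2:
        return "rejected", "aggregate"
    return "countable", "none"


def logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def confidence_factors(
    metrics: ComponentMetrics,
    criteria: CountingCriteria,
    contrast_snr: float,
    length_scale: float = 1.0,
    width_scale: float = 0.5,
    ar_scale: float = 1.0,
    snr_midpoint: float = 3.0,
    snr_scale: float = 1.0,
) -> dict[str, float]:
    """Individual logistic factors of the confidence score.

    Geometry factors sit at 0.5 exactly on each criterion boundary; the
    contrast factor is a logistic in the object-to-background
    signal-to-noise ratio.
    """
    return {
        "length": logistic((metrics.skeleton_length - criteria.L_min) / length_scale),
        "width": logistic((criteria.W_max - metrics.width) / width_scale),
        "aspect_ratio": logistic((metrics.aspect_ratio - criteria.AR_min) / ar_scale),
        "contrast": logistic((contrast_snr - snr_midpoint) / snr_scale),
    }


def confidence_score(
    metrics: ComponentMetrics,
    criteria: CountingCriteria,
    contrast_snr: float,
    **scales,
) -> float:
    """Product of the logistic margin factors; monotone in every margin."""
    f = confidence_factors(metrics, criteria, contrast_snr, **scales)
    return f["length"] * f["width"] * f["aspect_ratio"] * f["contrast"]


# ---------------------------------------------------------------------------
# Pipeline: segment -> measure -> classify -> confidence
# ---------------------------------------------------------------------------


def detect_fibers(
    image,
    config: DetectorConfig | None = None,
    criteria: CountingCriteria | None = None,
) -> tuple[list[DetectedFiber], int]:
    """Run the full detector on a composite image.

    Returns every candidate (countable and rejected) and the countable
    count N. A candidate is counted only if it passes the morphological
    criteria and its confidence clears ``confidence_threshold``.
    """
    config = config or DetectorConfig()
    criteria = criteria or CountingCriteria()
    raster, px = _as_raster(image)
    px = px or config.pixel_size
    labels = segment(image, config)
    n_labels = int(labels.max())
    detections: list[DetectedFiber] = []
    if n_labels == 0:
        return detections, 0
    sub = subtract_background(raster, int(round(config.bg_window_um / px)))
    sigma = max(_noise_sigma(sub), 1e-6)
    objects = ndi.find_objects(labels)
    for lab in range(1, n_labels + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        mask = labels[sl] == lab
        m = measure_component(mask, px, config.spur_prune_um)
        status, reason = classify_fiber(m, criteria)
        snr = float(sub[sl][mask].mean() / sigma)
        conf = confidence_score(m, criteria, snr)
        if status == "countable" and conf < config.confidence_threshold:
            status, reason = "rejected", "low_confidence"
        rows, cols = np.nonzero(mask)
        r0, c0 = sl[0].start, sl[1].start
        centroid = (
            float((cols.mean() + c0 + 0.5) * px),
            float((rows.mean() + r0 + 0.5) * px),
        )
        detections.append(
            DetectedFiber(
                bbox=(c0, r0, sl[1].stop, sl[0].stop),
                centroid_um=centroid,
                skeleton_length=m.skeleton_length,
                width=m.width,
                aspect_ratio=m.aspect_ratio,
                confidence=conf,
                status=status,
                reject_reason=reason,
                n_skeleton_endpoints=m.n_skeleton_endpoints,
                label=lab,
            )
        )
    n_countable = sum(1 for d in detections if d.status == "countable")
    return detections, n_countable


def background_flag(total_fluorescent_objects: int, threshold: int = 80) -> bool:
    """High false-positive-risk flag: strictly more objects than threshold.

    Raised when the total number of fluorescent objects in the analysed
    field exceeds the threshold (default 80), the regime in which clusters
    of contiguous particles start being misread as fibers.
    """
    if total_fluorescent_objects < 0:
        raise ParameterError("object count must be >= 0")
    return total_fluorescent_objects > threshold


def field_report(
    image,
    config: DetectorConfig | None = None,
    criteria: CountingCriteria | None = None,
) -> dict:
    """Per-field JSON-ready report: counts, rejections, background flag."""
    detections, n = detect_fibers(image, config, criteria)
    reasons: dict[str, int] = {}
    for d in detections:
        if d.status == "rejected":
            reasons[d.reject_reason] = reasons.get(d.reject_reason, 0) + 1
    return {
        "n_countable": n,
        "n_candidates": len(detections),
        "n_rejected_by_reason": reasons,
        "background_flag": background_flag(len(detections)),
    }


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------


def match_detections(
    detections: Sequence[DetectedFiber],
    truth_labels: Sequence[TruthLabel],
    particles: Sequence = (),
    max_centroid_dist: float = 3.0,
    pixel_size: float = 0.33,
) -> MatchResult:
    """Greedy one-to-one nearest-centroid matching of detections to truth.

    Countable detections pair with countable truth fibers within
    ``max_centroid_dist`` µm (closest pairs first). Unmatched countable
    detections are FP, unmatched countable truths FN, and truth particles
    not covered by any countable detection's box are TN.
    """
    if max_centroid_dist <= 0:
        raise ParameterError("max_centroid_dist must be positive")
    dets = [d for d in detections if d.status == "countable"]
    truths = [t for t in truth_labels if t.countable]
    cand = []
    for i, d in enumerate(dets):
        for j, t in enumerate(truths):
            dist = math.hypot(
                d.centroid_um[0] - t.fiber.centroid_xy[0],
                d.centroid_um[1] - t.fiber.centroid_xy[1],
            )
            if dist <= max_centroid_dist:
                cand.append((dist, i, j))
    cand.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    fp = len(dets) - tp
    fn = len(truths) - tp
    tn = 0
    for p in particles:
        x, y = p.centroid_xy
        covered = False
        for d in dets:
            x0, y0, x1, y1 = d.bbox  # pixels, half-open
            if (
                x0 * pixel_size <= x <= x1 * pixel_size
                and y0 * pixel_size <= y <= y1 * pixel_size
            ):
                covered = True
                break
        if not covered:
            tn += 1
    return MatchResult(tp=tp, fp=fp, fn=fn, tn=tn, pairs=pairs)


def detection_metrics(pairing: MatchResult) -> DetectionMetrics:
    """Precision, recall, F-score and accuracy from a pairing.

    Ratios with zero denominators are reported as None (absent), never 0.
    """
    tp, fp, fn, tn = pairing.tp, pairing.fp, pairing.fn, pairing.tn
    if min(tp, fp, fn, tn) < 0:
        raise InputError("confusion counts must be >= 0")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f_score = None
    if precision is not None and recall is not None and precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total if total > 0 else None
    return DetectionMetrics(tp, fp, fn, tn, precision, recall, f_score, accuracy)


# ---------------------------------------------------------------------------
# Dataset bookkeeping
# ---------------------------------------------------------------------------


def summarize_dataset(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-split image counts and mean objects per image (one decimal).

    ``annotations`` has one row per image with columns ``split``,
    ``n_fibers`` and ``n_particles``.
    """
    required = {"split", "n_fibers", "n_particles"}
    if not required.issubset(annotations.columns):
        raise InputError(f"annotations must have columns {sorted(required)}")
    if annotations.empty:
        raise InputError("empty annotation table")
    g = annotations.groupby("split")
    out = pd.DataFrame(
        {
            "n_images": g.size(),
            "fibers_per_image": g["n_fibers"].mean().round(1),
            "particles_per_image": g["n_particles"].mean().round(1),
        }
    )
    return out


@dataclass
class SplitAssignment:
    """Random image-level dataset split with per-split percentages."""

    assignment: np.ndarray  # split index per image
    names: tuple[str, ...]
    fractions: tuple[float, ...]  # percent, one decimal place


def split_dataset(
    n_images: int,
    split_sizes: Sequence[int],
    seed: int,
    names: Sequence[str] = ("train", "val", "test"),
) -> SplitAssignment:
    """Randomly assign images to splits of the given sizes."""
    sizes = [int(s) for s in split_sizes]
    if any(s < 0 for s in sizes):
        raise InputError("split sizes must be >= 0")
    if sum(sizes) != n_images:
        raise InputError(f"split sizes {sizes} do not sum to n_images={n_images}")
    names = tuple(names)[: len(sizes)]
    if len(names) < len(sizes):
        names = names + tuple(f"split{i}" for i in range(len(names), len(sizes)))
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(n_images)
    assignment = np.empty(n_images, dtype=np.intp)
    start = 0
    for idx, s in enumerate(sizes):
        assignment[order[start : start + s]] = idx
        start += s
    fractions = tuple(round(100.0 * s / n_images, 1) for s in sizes)
    return SplitAssignment(assignment=assignment, names=names, fractions=fractions)
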