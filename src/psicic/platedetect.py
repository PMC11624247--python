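"""Colony localization on segmentation masks, plus color normalization.

Colonies appear circular, so detection runs a circle Hough transform on the
edge map of the binarized colony-vs-background mask: accumulator peaks over
a radius range give (center, radius, score) hypotheses with overlapping
detections suppressed. Detections whose centers fall too close to the image
border (default 150 px at 1024x1024, scaled proportionally) are excluded
before square per-colony crops are taken from both the image and its mask.

Color transfer (for plates photographed under a different cast) matches the
per-channel first and second moments of the image to a reference in the
decorrelated log-opponent l-alpha-beta color space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.transform import hough_circle, hough_circle_peaks

from .masks import BACKGROUND

__all__ = [
    "CircleDetection",
    "ColonyCrop",
    "DetectionCounts",
    "color_transfer",
    "detect_colonies",
    "exclude_border",
    "scaled_border_margin",
    "crop_colony",
    "greedy_matches",
    "match_detections",
]


@dataclass(frozen=True)
class CircleDetection:
    """One detected colony hypothesis."""

    center: tuple[int, int]  # (row, col), 0-based
    radius: float
    score: float


@dataclass
class ColonyCrop:
    image: np.ndarray  # square (S, S, 3) patch
    mask: np.ndarray  # square (S, S) label-mask patch
    circle: CircleDetection
    offset: tuple[int, int]  # (row, col) of patch origin in plate coordinates


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fn: int
    fp: int


# --- color transfer ---------------------------------------------------------

_RGB2LMS = np.array(
    [[0.3811, 0.5783, 0.0402], [0.1967, 0.7244, 0.0782], [0.0241, 0.1288, 0.8444]]
)
_LMS2LAB = np.diag([1 / math.sqrt(3), 1 / math.sqrt(6), 1 / math.sqrt(2)]) @ np.array(
    [[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]]
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LOG_EPS = 1e-6


def _rgb_to_lab(img: np.ndarray) -> np.ndarray:
    lms = np.clip(img.astype(np.float64) / 255.0, 0, 1) @ _RGB2LMS.T
    return np.log10(lms + _LOG_EPS) @ _LMS2LAB.T


def _lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    lms = np.power(10.0, lab @ _LAB2LMS.T) - _LOG_EPS
    rgb = lms @ _LMS2RGB.T
    return np.clip(rgb * 255.0, 0, 255)


def color_transfer(image: np.ndarray, reference_image: np.ndarray) -> np.ndarray:
    """Match the image's color statistics to those of a reference image.

    In the decorrelated l-alpha-beta space, each channel is rescaled so its
    mean and standard deviation equal the reference's. A reference with a
    zero-variance channel is degenerate and rejected.
    """
    src = _rgb_to_lab(np.asarray(image))
    ref = _rgb_to_lab(np.asarray(reference_image))
    s_mu, s_sd = src.reshape(-1, 3).mean(0), src.reshape(-1, 3).std(0)
    r_mu, r_sd = ref.reshape(-1, 3).mean(0), ref.reshape(-1, 3).std(0)
    if np.any(r_sd < 1e-12):
        raise ValueError("degenerate reference: zero-variance color channel")
    s_sd = np.where(s_sd < 1e-12, 1.0, s_sd)
    out = (src - s_mu) * (r_sd / s_sd) + r_mu
    return _lab_to_rgb(out).round().astype(np.uint8)


# --- circle Hough detection -------------------------------------------------


def detect_colonies(
    mask: np.ndarray,
    radius_range: tuple[float, float],
    peak_threshold: float = 0.4,
    min_distance_factor: float = 1.5,
    max_detections: int | None = None,
) -> list[CircleDetection]:
    """Detect circular colonies on a label mask via the circle Hough transform.

    The mask is binarized (colony vs background), its morphological gradient
    taken as the edge map, and a Hough accumulator built for integer radii
    spanning ``radius_range``. Peaks below ``peak_threshold`` of the maximum
    are dropped and peaks closer than ``min_distance_factor * min_radius``
    suppressed. Returns detections sorted by descending accumulator score.
    """
    binary = np.asarray(mask) != BACKGROUND
    if not binary.any():
        return []
    edges = binary & ~binary_erosion(binary, structure=np.ones((3, 3), bool))
    rmin, rmax = radius_range
    radii = np.arange(max(1, int(round(rmin))), int(round(rmax)) + 1)
    accums = hough_circle(edges, radii)
    min_dist = max(1, int(round(min_distance_factor * rmin)))
    n_peaks = max_detections if max_detections is not None else np.inf
    scores, cxs, cys, rs = hough_circle_peaks(
        accums,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=peak_threshold * float(accums.max()),
        total_num_peaks=n_peaks,
    )
    dets = [
        CircleDetection(center=(int(cy), int(cx)), radius=float(r), score=float(s))
        for s, cx, cy, r in zip(scores, cxs, cys, rs)
    ]
    return sorted(dets, key=lambda d: -d.score)


def scaled_border_margin(image_size: int, base_margin: int = 150, base_size: int = 1024) -> int:
    """The border-exclusion margin, 150 px at 1024², scaled proportionally."""
    return int(round(base_margin * image_size / base_size))


def exclude_border(
    circles: list[CircleDetection], image_size: int, margin: int
) -> tuple[list[CircleDetection], list[CircleDetection]]:
    """Partition detections by distance of their center from the image edges.

    A detection is kept iff its center lies at distance >= ``margin`` from
    every edge of the (square) image; the rest are excluded.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    kept, excluded = [], []
    for c in circles:
        row, col = c.center
        edge_dist = min(row, col, image_size - 1 - row, image_size - 1 - col)
        (kept if edge_dist >= margin else excluded).append(c)
    return kept, excluded


def crop_colony(
    plate_image: np.ndarray,
    plate_mask: np.ndarray,
    circle: CircleDetection,
    pad_factor: float = 1.5,
) -> ColonyCrop:
    """Cut a square, odd-sided patch centered on the detected colony center.

    Side length is ceil(2 * radius * pad_factor), bumped to odd so the center
    pixel is unique. Mask pixels outside the detected circle are retained:
    the annotation stage delimits the colony by mask labels, not the circle.
    """
    side = int(math.ceil(2 * circle.radius * pad_factor))
    if side % 2 == 0:
        side += 1
    half = side // 2
    row, col = circle.center
    r0, c0 = row - half, col - half
    r1, c1 = row + half + 1, col + half + 1
    h, w = plate_mask.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"crop of side {side} at center {circle.center} leaves the image "
            f"({h}x{w}); exclude border detections first"
        )
    return ColonyCrop(
        image=np.ascontiguousarray(plate_image[r0:r1, c0:c1]),
        mask=np.ascontiguousarray(plate_mask[r0:r1, c0:c1]),
        circle=circle,
        offset=(r0, c0),
    )


def greedy_matches(detections: list[CircleDetection], layout) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections against ground-truth colonies.

    Detections (highest score first) claim the nearest unmatched true colony
    whose center lies within that colony's radius. Returns (detection index,
    truth index) pairs in the original ``detections`` indexing.
    """
    truths = list(layout)
    taken = [False] * len(truths)
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    pairs = []
    for di in order:
        det = detections[di]
        best, best_dist = None, np.inf
        for i, t in enumerate(truths):
            if taken[i]:
                continue
            d = math.hypot(det.center[0] - t.center[0], det.center[1] - t.center[1])
            if d <= t.radius and d < best_dist:
                best, best_dist = i, d
        if best is not None:
            taken[best] = True
            pairs.append((di, best))
    return pairs


def match_detections(detections: list[CircleDetection], layout) -> DetectionCounts:
    """Detection confusion counts (TP, FN, FP) via `greedy_matches`."""
    pairs = greedy_matches(detections, layout)
    tp = len(pairs)
    return DetectionCounts(tp=tp, fn=len(list(layout)) - tp, fp=len(detections) - tp)
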