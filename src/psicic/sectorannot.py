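"""Idealized-sector annotation of a single colony's label mask.

A sectored colony records prion-loss events as red ([psi-]) wedges inside an
otherwise white ([PSI+]) colony. Assuming each red or white patch grows
radially from the colony center with straight edges, the colony partitions
into "idealized sectors": wedges bounded by a colony-boundary arc and two
radii joining the arc's endpoints to the center.

The annotation proceeds in stages:

1. Split the colony mask into boundary (colony pixels 8-adjacent to
   background) and interior; thin the boundary to a 1-px skeleton that keeps
   the original red/white pixel labels.
2. Find the 8-connected components of red and white skeleton pixels
   separately; each open component is one arc with two endpoints (located as
   the union of hit-or-miss endpoint templates and a brute-force scan for
   pixels with exactly one neighbor in the component).
3. Close each arc into a wedge with two center-to-endpoint radii and assign
   every colony pixel to exactly one wedge by its polar angle about the
   center (pixels on a dividing line go with the region counterclockwise of
   it, via half-open angular intervals).
4. Score each region with the purity p = (pixels matching the region's
   color) / (all colony pixels in the region), weight regions by size, and
   pool into the weighted colony purity p_w.
5. Purity correction: while any region has p < 0.5, flip the colors of that
   region's arc pixels, re-merge adjacent same-color arcs, rebuild the
   regions, and rescore. By the mediant inequality a merge of regions each
   with p >= 0.5 keeps pooled purity >= 0.5, so the loop terminates at an
   annotation whose regions all satisfy the purity constraint (or is flagged
   non-convergent at an iteration cap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize
from sklearn.base import BaseEstimator, TransformerMixin

from .masks import BACKGROUND, RED, WHITE, validate_mask

__all__ = [
    "Unquantifiable",
    "BoundaryComponent",
    "Region",
    "ColonyAnnotation",
    "split_boundary_interior",
    "boundary_components",
    "find_endpoints",
    "build_regions",
    "purity",
    "weighted_purity",
    "pooled_purity",
    "purity_correct",
    "select_central_colony",
    "annotate_colony",
    "bresenham_line",
    "render_annotation",
    "SectorAnnotator",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_NEIGHBOR_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

PURITY_THRESHOLD = 0.5
DEFAULT_MAX_CORRECTION_ITER = 20


class Unquantifiable(Exception):
    """Raised when a colony cannot be annotated cleanly.

    ``reason`` is one of: empty, branched_boundary, ill_defined_regions,
    non_convergent.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass
class BoundaryComponent:
    """One connected monochrome arc of the skeletonized colony boundary."""

    color: int  # RED or WHITE label code
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    shape: tuple[int, int]  # shape of the source mask
    endpoints: list[tuple[int, int]] = field(default_factory=list)

    def as_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class Region:
    """One idealized sector with its pixel counts N(., red) / N(., white)."""

    color: int
    arc: BoundaryComponent
    n_red: int
    n_white: int
    purity: float  # p, fraction of region pixels matching `color`
    weight: float  # mu, region size / colony size
    angular_interval: tuple[float, float]  # [start, end) degrees, CCW

    @property
    def size(self) -> int:
        return self.n_red + self.n_white


@dataclass
class ColonyAnnotation:
    """The set of regions partitioning one colony, with summary statistics.

    ``a`` and ``b`` are the red and white region counts; ``weighted_purity``
    is p_w, the size-weighted mean of region purities (equal to the pooled
    matching-pixel fraction).
    """

    regions: list[Region] = field(default_factory=list)
    a: int = 0
    b: int = 0
    N_R: int = 0
    N_W: int = 0
    weighted_purity: float = 0.0
    correction_iterations: int = 0
    status: str = "ok"
    reason: str = ""
    region_map: np.ndarray | None = None  # per-pixel region index, -1 = background
    corrected_mask: np.ndarray | None = None  # mask with arc flips applied

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "reason": self.reason,
            "a": self.a,
            "b": self.b,
            "N_R": self.N_R,
            "N_W": self.N_W,
            "weighted_purity": self.weighted_purity,
            "correction_iterations": self.correction_iterations,
            "regions": [
                {
                    "color": "red" if r.color == RED else "white",
                    "n_red": r.n_red,
                    "n_white": r.n_white,
                    "purity": r.purity,
                    "weight": r.weight,
                    "angular_interval": list(r.angular_interval),
                }
                for r in self.regions
            ],
        }


# --- boundary / interior ----------------------------------------------------


def split_boundary_interior(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a colony mask into a 1-px boundary skeleton and the interior.

    Boundary pixels are colony pixels with at least one background
    8-neighbor (pixels beyond the image edge count as background); the
    boundary set is thinned to unit width while its pixels keep their
    red/white labels. Returns ``(skeleton, interior)`` boolean arrays whose
    union is exactly the colony pixel set.
    """
    mask = validate_mask(mask)
    colony = mask != BACKGROUND
    if not colony.any():
        raise Unquantifiable("empty", "no colony pixels in mask")
    bg = np.pad(~colony, 1, constant_values=True)
    adj_bg = ndi.binary_dilation(bg, structure=_STRUCT8)[1:-1, 1:-1]
    boundary = colony & adj_bg
    skel = skeletonize(boundary)
    if not skel.any():
        # skeletonize can annihilate single-pixel specks; keep the boundary
        skel = boundary
    interior = colony & ~skel
    return skel, interior


def boundary_components(skeleton: np.ndarray, mask: np.ndarray) -> list[BoundaryComponent]:
    """8-connected components of red and white skeleton pixels, per color."""
    comps: list[BoundaryComponent] = []
    for color in (RED, WHITE):
        m = skeleton & (mask == color)
        labels, n = ndi.label(m, structure=_STRUCT8)
        for i in range(1, n + 1):
            pixels = np.argwhere(labels == i)
            comp = BoundaryComponent(color=color, pixels=pixels, shape=mask.shape)
            comp.endpoints = find_endpoints(comp)
            comps.append(comp)
    return comps


def _neighbor_counts(m: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndi.convolve(m.astype(int), kernel, mode="constant", cval=0)


def find_endpoints(component: BoundaryComponent) -> list[tuple[int, int]]:
    """Arc endpoints: union of hit-or-miss templates and a brute-force scan.

    The brute-force scan marks pixels with exactly one 8-neighbor inside the
    component; the hit-or-miss pass applies the eight endpoint structuring
    elements (one required neighbor, the remaining seven required empty).
    A closed loop yields no endpoints; more than two endpoints means the
    skeleton branches and the colony is not quantifiable.
    """
    m = component.as_mask()
    if m.sum() == 1:
        p = tuple(int(v) for v in component.pixels[0])
        return [p]
    brute = m & (_neighbor_counts(m) == 1)
    hitmiss = np.zeros_like(m)
    for dr, dc in _NEIGHBOR_OFFSETS:
        s1 = np.zeros((3, 3), dtype=int)
        s1[1, 1] = 1
        s1[1 + dr, 1 + dc] = 1
        s2 = np.ones((3, 3), dtype=int) - s1
        s2[1, 1] = 0
        hitmiss |= ndi.binary_hit_or_miss(m, structure1=s1, structure2=s2)
    union = brute | hitmiss
    endpoints = [tuple(int(v) for v in rc) for rc in np.argwhere(union)]
    if len(endpoints) > 2:
        raise Unquantifiable(
            "branched_boundary", f"{len(endpoints)} endpoints on one boundary arc"
        )
    return endpoints


# --- region construction ----------------------------------------------------


def _angles_deg(pixels: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    dy = pixels[..., 0] - center[0]
    dx = pixels[..., 1] - center[1]
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def _arc_interval(angles: np.ndarray) -> tuple[float, float]:
    """Angular interval spanned by an arc: the complement of its largest gap."""
    s = np.sort(np.asarray(angles, dtype=float))
    if s.size == 1:
        return float(s[0]), float(s[0])
    gaps = np.diff(s)
    wrap_gap = s[0] + 360.0 - s[-1]
    i = int(np.argmax(gaps)) if gaps.size else 0
    if wrap_gap >= (gaps[i] if gaps.size else -np.inf):
        return float(s[0]), float(s[-1])
    return float(s[i + 1]), float(s[i])


def _resolve_endpoints(comp: BoundaryComponent) -> None:
    """Ensure an open arc exposes exactly two endpoints.

    A single-endpoint component (corner artifact) has its endpoint paired
    with the arc pixel farthest from it.
    """
    if len(comp.endpoints) == 1:
        e = np.array(comp.endpoints[0])
        d = np.hypot(*(comp.pixels - e).T)
        far = comp.pixels[int(np.argmax(d))]
        comp.endpoints = [tuple(int(v) for v in e), tuple(int(v) for v in far)]


def build_regions(
    mask: np.ndarray, components: list[BoundaryComponent], center: tuple[float, float]
) -> ColonyAnnotation:
    """Partition the colony into idealized sectors, one per boundary arc.

    Each open arc is closed by two center-to-endpoint radii; each colony
    pixel joins the region whose angular interval (half-open, CCW) contains
    its polar angle about the center. A single closed-loop boundary gives a
    single region covering the whole colony.
    """
    mask = validate_mask(mask)
    colony = mask != BACKGROUND
    total = int(colony.sum())
    if total == 0 or not components:
        raise Unquantifiable("empty")

    pix = np.argwhere(colony)
    red_flags = mask[pix[:, 0], pix[:, 1]] == RED

    k = len(components)
    closed = [len(c.endpoints) == 0 and len(c.pixels) > 1 for c in components]
    if k == 1 and (closed[0] or len(components[0].pixels) <= 2):
        region_idx = np.zeros(len(pix), dtype=int)
        intervals = [(0.0, 360.0)]
        order = [0]
    else:
        if any(closed):
            raise Unquantifiable(
                "ill_defined_regions", "closed boundary loop alongside other arcs"
            )
        for c in components:
            _resolve_endpoints(c)
        intervals_raw = [_arc_interval(_angles_deg(c.pixels, center)) for c in components]
        order = sorted(range(k), key=lambda i: intervals_raw[i][0])
        # cut between consecutive arcs: midpoint of the gap facing them
        cuts = []
        for pos in range(k):
            i, j = order[pos], order[(pos + 1) % k]
            end_i = intervals_raw[i][1]
            start_j = intervals_raw[j][0]
            gap = (start_j - end_i) % 360.0
            cuts.append((end_i + gap / 2.0) % 360.0)
        sc = np.sort(np.asarray(cuts))
        # map each arc to the slot its interval midpoint falls in
        slot_of: dict[int, int] = {}
        for pos in range(k):
            i = order[pos]
            a, b = intervals_raw[i]
            mid = (a + ((b - a) % 360.0) / 2.0) % 360.0
            slot = int(np.searchsorted(sc, mid, side="right") % k)
            if slot in slot_of.values():
                raise Unquantifiable("ill_defined_regions", "overlapping arc intervals")
            slot_of[i] = slot
        ang = _angles_deg(pix, center)
        pixel_slot = np.searchsorted(sc, ang, side="right") % k
        slot_to_region = np.empty(k, dtype=int)
        for comp_i, slot in slot_of.items():
            slot_to_region[slot] = comp_i
        region_idx = slot_to_region[pixel_slot]
        # regions are reported in CCW order of their interval start
        intervals = []
        for pos in range(k):
            i = order[pos]
            start = sc[(slot_of[i] - 1) % k]
            end = sc[slot_of[i]]
            intervals.append((float(start), float(end)))
        intervals = [intervals[order.index(i)] for i in range(k)]

    n_red = np.bincount(region_idx[red_flags], minlength=k)
    n_white = np.bincount(region_idx[~red_flags], minlength=k)
    sizes = n_red + n_white
    if np.any(sizes == 0):
        raise Unquantifiable("ill_defined_regions", "region with no pixels")

    regions = []
    for i, comp in enumerate(components):
        p = purity_from_counts(comp.color, int(n_red[i]), int(n_white[i]))
        regions.append(
            Region(
                color=comp.color,
                arc=comp,
                n_red=int(n_red[i]),
                n_white=int(n_white[i]),
                purity=p,
                weight=float(sizes[i] / total),
                angular_interval=intervals[i],
            )
        )

    region_map = np.full(mask.shape, -1, dtype=int)
    region_map[pix[:, 0], pix[:, 1]] = region_idx
    ann = ColonyAnnotation(
        regions=regions,
        a=sum(1 for r in regions if r.color == RED),
        b=sum(1 for r in regions if r.color == WHITE),
        N_R=int(sizes[[i for i, r in enumerate(regions) if r.color == RED]].sum()),
        N_W=int(sizes[[i for i, r in enumerate(regions) if r.color == WHITE]].sum()),
        weighted_purity=pooled_purity(regions),
        region_map=region_map,
        corrected_mask=mask.copy(),
    )
    return ann


# --- purity -----------------------------------------------------------------


def purity_from_counts(color: int, n_red: int, n_white: int) -> float:
    total = n_red + n_white
    if total == 0:
        raise ValueError("purity of an empty region is undefined")
    return (n_red if color == RED else n_white) / total


def purity(region: Region) -> float:
    """Fraction of the region's colony pixels matching the region's color."""
    return purity_from_counts(region.color, region.n_red, region.n_white)


def weighted_purity(regions: list[Region]) -> float:
    """Colony purity p_w as the size-weighted average of region purities."""
    return float(sum(purity(r) * r.weight for r in regions))


def pooled_purity(regions: list[Region]) -> float:
    """Colony purity p_w as the pooled matching-pixel fraction.

    Algebraically identical to `weighted_purity`; both forms are kept so the
    identity can be verified numerically.
    """
    matching = sum(r.n_red if r.color == RED else r.n_white for r in regions)
    total = sum(r.size for r in regions)
    return matching / total


# --- purity correction ------------------------------------------------------


def purity_correct(
    annotation: ColonyAnnotation,
    mask: np.ndarray,
    center: tuple[float, float],
    max_iter: int = DEFAULT_MAX_CORRECTION_ITER,
) -> ColonyAnnotation:
    """Iteratively flip sub-0.5-purity arcs and merge same-color neighbors.

    Each pass flips the arc pixels of every region with p < 0.5 to the
    opposite color, recomputes the boundary components (adjacent same-color
    arcs merge into one), rebuilds the regions and their purities. Stops at
    a fixed point where every region has p >= 0.5; an annotation already at
    the fixed point is returned unchanged. Exceeding ``max_iter`` flags the
    colony unquantifiable(non_convergent).
    """
    if not annotation.ok:
        return annotation
    if all(r.purity >= PURITY_THRESHOLD for r in annotation.regions):
        return annotation

    work = (annotation.corrected_mask if annotation.corrected_mask is not None else mask).copy()
    skel = np.zeros(work.shape, dtype=bool)
    for r in annotation.regions:
        skel[r.arc.pixels[:, 0], r.arc.pixels[:, 1]] = True

    ann = annotation
    iterations = 0
    try:
        while True:
            impure = [r for r in ann.regions if r.purity < PURITY_THRESHOLD]
            if not impure:
                break
            if iterations >= max_iter:
                raise Unquantifiable("non_convergent", f"no fixed point in {max_iter} passes")
            for r in impure:
                rows, cols = r.arc.pixels[:, 0], r.arc.pixels[:, 1]
                work[rows, cols] = WHITE if r.color == RED else RED
            comps = boundary_components(skel, work)
            ann = build_regions(work, comps, center)
            iterations += 1
    except Unquantifiable as exc:
        return ColonyAnnotation(status="unquantifiable", reason=exc.reason)
    ann.correction_iterations = annotation.correction_iterations + iterations
    return ann


def select_central_colony(mask: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Blank out colony pixels not belonging to the colony at ``center``.

    A crop is centered on one detected colony but may clip fragments of
    neighboring colonies in its corners; only the 8-connected component of
    colony pixels containing (or nearest to) the center is the colony under
    annotation.
    """
    colony = mask != BACKGROUND
    labels, n = ndi.label(colony, structure=_STRUCT8)
    if n <= 1:
        return mask
    cr, cc = int(round(center[0])), int(round(center[1]))
    cr = min(max(cr, 0), mask.shape[0] - 1)
    cc = min(max(cc, 0), mask.shape[1] - 1)
    target = labels[cr, cc]
    if target == 0:
        pix = np.argwhere(colony)
        d = np.hypot(pix[:, 0] - center[0], pix[:, 1] - center[1])
        target = labels[tuple(pix[int(np.argmin(d))])]
    out = mask.copy()
    out[colony & (labels != target)] = BACKGROUND
    return out


def annotate_colony(
    mask: np.ndarray,
    center: tuple[float, float] | None = None,
    correct: bool = True,
    max_iter: int = DEFAULT_MAX_CORRECTION_ITER,
) -> ColonyAnnotation:
    """Full annotation of one colony crop: regions, purities, correction.

    ``center`` defaults to the crop's center pixel (the detection stage
    centers each crop on the detected colony center). Fragments of
    neighboring colonies clipped by the crop are discarded via
    `select_central_colony`. Failures surface as an annotation with
    ``status == "unquantifiable"`` rather than exceptions.
    """
    try:
        mask = validate_mask(mask)
        if center is None:
            center = ((mask.shape[0] - 1) / 2.0, (mask.shape[1] - 1) / 2.0)
        mask = select_central_colony(mask, center)
        skel, _ = split_boundary_interior(mask)
        comps = boundary_components(skel, mask)
        ann = build_regions(mask, comps, center)
        if correct:
            ann = purity_correct(ann, mask, center, max_iter=max_iter)
        return ann
    except Unquantifiable as exc:
        return ColonyAnnotation(status="unquantifiable", reason=exc.reason)


# --- audit rendering --------------------------------------------------------


def bresenham_line(p0: tuple[int, int], p1: tuple[int, int]) -> list[tuple[int, int]]:
    """Integer pixel coordinates of the line from p0 to p1 (inclusive)."""
    r0, c0 = int(p0[0]), int(p0[1])
    r1, c1 = int(p1[0]), int(p1[1])
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r0 < r1 else -1
    sc = 1 if c0 < c1 else -1
    err = dr - dc
    out = []
    while True:
        out.append((r0, c0))
        if (r0, c0) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r0 += sr
        if e2 < dr:
            err += dr
            c0 += sc
    return out


def render_annotation(mask: np.ndarray, annotation: ColonyAnnotation) -> np.ndarray:
    """RGB overlay of an annotation for visual audit.

    Region interiors are tinted by their color call, arcs drawn saturated,
    and the dividing radii drawn as black Bresenham lines to the center.
    """
    h, w = mask.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    if annotation.region_map is None:
        return out
    center = ((h - 1) // 2, (w - 1) // 2)
    for i, r in enumerate(annotation.regions):
        sel = annotation.region_map == i
        out[sel] = (220, 120, 110) if r.color == RED else (230, 230, 220)
        out[r.arc.pixels[:, 0], r.arc.pixels[:, 1]] = (
            (200, 30, 30) if r.color == RED else (250, 250, 250)
        )
        for ep in r.arc.endpoints:
            for rr, cc in bresenham_line(ep, center):
                if 0 <= rr < h and 0 <= cc < w:
                    out[rr, cc] = (0, 0, 0)
    return out


class SectorAnnotator(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer: label masks -> annotations.

    ``transform`` maps a sequence of colony-crop label masks to
    `ColonyAnnotation` objects; ``predict`` maps them further to phenotype
    labels ("PSI+", "psi-", "S{k}", or "unquantifiable").
    """

    def __init__(self, correct: bool = True, max_iter: int = DEFAULT_MAX_CORRECTION_ITER):
        self.correct = correct
        self.max_iter = max_iter

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return [annotate_colony(m, correct=self.correct, max_iter=self.max_iter) for m in X]

    def predict(self, X):
        from .classify_eval import assign_class

        out = []
        for ann in self.transform(X):
            out.append(assign_class(ann).label if ann.ok else "unquantifiable")
        return out
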