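"""Synthetic plate images of sectored yeast colonies with exact ground truth.

Renders plates the way they appear in experimental photographs of
*S. cerevisiae* prion assays: a dark table, a lighter agar plate with a
border ring carrying small aberrations, and circular colonies. Each colony is
a white disk ([PSI+]-colored) over which red angular sectors ([psi-]-colored)
are overlaid from the center to the rim. Two pixel-exact ground-truth masks
accompany every image:

* a 3-class label mask (background / red colony / white colony), obtained by
  exact color identity against the two representative colony colors on the
  clean render, and
* a sector-count mask holding a small disk at each colony center whose
  intensity increases with the number of sectors.

Per-pixel Poisson shot noise is applied to the image *after* the masks are
made, so the masks stay exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import masks
from .masks import BACKGROUND, RED, WHITE

__all__ = [
    "Palette",
    "PlateSpec",
    "ColonyLayout",
    "SyntheticPlate",
    "sample_layout",
    "render_plate",
    "apply_poisson_noise",
    "generate_plate",
    "generate_plates",
    "layout_truth_label",
    "scaled_spec",
    "write_plate",
    "load_layout",
]

# intensity step of the sector-count mask: disk value = step * (n_sectors + 1)
COUNT_MASK_STEP = 40
COUNT_MASK_RADIUS = 5

# plate geometry as fractions of the image side
_PLATE_OUTER_FRAC = 0.48
_PLATE_INNER_FRAC = 0.46


@dataclass(frozen=True)
class Palette:
    """Representative colors (RGB, 0-255) for the five scene elements."""

    white_colony: tuple[int, int, int] = (235, 225, 210)
    red_sector: tuple[int, int, int] = (185, 60, 55)
    plate: tuple[int, int, int] = (250, 245, 235)
    table: tuple[int, int, int] = (60, 60, 60)
    border: tuple[int, int, int] = (200, 196, 188)  # plate darkened ~20%

    def validate(self) -> None:
        colors = [self.white_colony, self.red_sector, self.plate, self.table, self.border]
        for c in colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"invalid RGB color {c}")
        if self.white_colony == self.red_sector:
            raise ValueError("white_colony and red_sector colors must differ")
        for other in (self.plate, self.table, self.border):
            if other in (self.white_colony, self.red_sector):
                raise ValueError("background colors must differ from colony colors")


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of one synthetic plate.

    ``radius_range`` and ``sector_angle_range`` are inclusive (min, max)
    bounds in pixels and degrees respectively. With the defaults, 100
    colonies of radius 18-28 px cover roughly a quarter of the plate
    interior at 1024x1024, which places reliably under rejection sampling.
    """

    image_size: int = 1024
    n_colonies: int = 100
    radius_range: tuple[float, float] = (18.0, 28.0)
    sectors_per_colony: int = 1
    sector_angle_range: tuple[float, float] = (20.0, 120.0)
    palette: Palette = field(default_factory=Palette)
    noise_enabled: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if self.image_size <= 2 * rmax:
            raise ValueError("image_size must exceed twice the max radius")
        amin, amax = self.sector_angle_range
        if not (0 < amin <= amax < 360):
            raise ValueError("sector_angle_range must lie within (0, 360)")
        if self.n_colonies < 0:
            raise ValueError("n_colonies must be >= 0")
        if self.sectors_per_colony < 0:
            raise ValueError("sectors_per_colony must be >= 0")
        self.palette.validate()

    @property
    def plate_center(self) -> tuple[float, float]:
        return (self.image_size / 2.0, self.image_size / 2.0)

    @property
    def plate_outer_radius(self) -> float:
        return _PLATE_OUTER_FRAC * self.image_size

    @property
    def plate_inner_radius(self) -> float:
        return _PLATE_INNER_FRAC * self.image_size


@dataclass(frozen=True)
class ColonyLayout:
    """Ground-truth record of one colony: center (row, col), radius in px,
    and a list of half-open angular sector intervals [start, end) in degrees.

    Angles are measured as ``atan2(row - center_row, col - center_col)``
    reduced mod 360, consistently with the annotation stage.
    """

    center: tuple[float, float]
    radius: float
    sectors: tuple[tuple[float, float], ...] = ()


@dataclass
class SyntheticPlate:
    image: np.ndarray  # (H, W, 3) uint8, noisy if spec.noise_enabled
    class_mask: np.ndarray  # (H, W) uint8 codes {0, 128, 255}
    count_mask: np.ndarray  # (H, W) uint8
    layout: list[ColonyLayout]
    clean_image: np.ndarray | None = None  # pre-noise render


def scaled_spec(image_size: int = 256, rng_seed: int = 0, **overrides) -> PlateSpec:
    """A PlateSpec with geometry scaled from the 1024-pixel defaults.

    Colony count is reduced (and radii enlarged relative to strict scaling)
    at small sizes so each colony keeps enough pixels for sector annotation;
    this is the package's reduced-resolution test profile.
    """
    s = image_size / 1024.0
    if image_size <= 160:
        n, rr = 6, (10.0, 14.0)
    elif image_size <= 384:
        n, rr = 25, (12.0, 18.0)
    else:
        n, rr = 100, (18.0 * s, 28.0 * s)
    defaults = dict(
        image_size=image_size,
        n_colonies=n,
        radius_range=rr,
        rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return PlateSpec(**defaults)


def _stage_rng(spec: PlateSpec, stage: int) -> np.random.Generator:
    # independent streams per stage so layout is invariant to noise settings
    return np.random.default_rng([int(spec.rng_seed) % (2**31), stage])


def _sample_sectors(rng: np.random.Generator, spec: PlateSpec) -> tuple[tuple[float, float], ...]:
    """Draw ``sectors_per_colony`` pairwise-disjoint angular intervals."""
    k = spec.sectors_per_colony
    if k == 0:
        return ()
    amin, amax = spec.sector_angle_range
    for _ in range(200):
        widths = rng.uniform(amin, amax, size=k)
        if widths.sum() >= 360.0:
            continue
        starts = rng.uniform(0.0, 360.0, size=k)
        ivs = sorted((float(s), float(w)) for s, w in zip(starts, widths))
        ok = True
        for i in range(k):
            s_i, w_i = ivs[i]
            s_j, _ = ivs[(i + 1) % k]
            gap = (s_j - s_i) % 360.0 if k > 1 else 360.0
            if gap < w_i:
                ok = False
                break
        if ok:
            return tuple((s, (s + w) % 360.0) for s, w in ivs)
    raise RuntimeError(
        f"could not place {k} disjoint sectors with widths in "
        f"{spec.sector_angle_range} after 200 attempts"
    )


def sample_layout(spec: PlateSpec) -> list[ColonyLayout]:
    """Place ``n_colonies`` pairwise-disjoint colony disks on the plate.

    Uniform rejection sampling inside the plate interior with a minimum
    inter-center gap of ``r_i + r_j + 2`` px. Deterministic given
    ``spec.rng_seed``.
    """
    spec.validate()
    rng = _stage_rng(spec, 0)
    cy, cx = spec.plate_center
    inner = spec.plate_inner_radius
    rmin, rmax = spec.radius_range

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = max(1000, 400 * spec.n_colonies)
    attempts = 0
    while len(centers) < spec.n_colonies:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {len(centers)}/{spec.n_colonies} colonies after "
                f"{max_attempts} attempts: colony density too high for plate "
                f"interior radius {inner:.0f} px with radii in {spec.radius_range}"
            )
        attempts += 1
        r = float(rng.uniform(rmin, rmax))
        row = float(rng.uniform(cy - inner, cy + inner))
        col = float(rng.uniform(cx - inner, cx + inner))
        if math.hypot(row - cy, col - cx) + r > inner - 2:
            continue
        if any(
            math.hypot(row - pr, col - pc) < r + pradius + 2
            for (pr, pc), pradius in zip(centers, radii)
        ):
            continue
        centers.append((row, col))
        radii.append(r)

    return [
        ColonyLayout(center=c, radius=r, sectors=_sample_sectors(rng, spec))
        for c, r in zip(centers, radii)
    ]


def _angle_deg(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def _in_interval(angles: np.ndarray, start: float, end: float) -> np.ndarray:
    """Membership in the half-open angular interval [start, end) mod 360."""
    return ((angles - start) % 360.0) < ((end - start) % 360.0 or 360.0)


def render_plate(spec: PlateSpec, layout: list[ColonyLayout]) -> SyntheticPlate:
    """Render the plate scene, the two ground-truth masks, and apply noise."""
    spec.validate()
    n = spec.image_size
    pal = spec.palette
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy, cx = spec.plate_center
    dist = np.hypot(yy - cy, xx - cx)

    img = np.empty((n, n, 3), dtype=np.uint8)
    img[:] = pal.table
    img[dist <= spec.plate_outer_radius] = pal.plate
    ring = (dist > spec.plate_inner_radius) & (dist <= spec.plate_outer_radius)
    img[ring] = pal.border

    # border aberrations: small darker blotches confined to the ring
    rng = _stage_rng(spec, 1)
    n_blotch = max(6, n // 40)
    mid_r = 0.5 * (spec.plate_inner_radius + spec.plate_outer_radius)
    for _ in range(n_blotch):
        theta = rng.uniform(0, 2 * math.pi)
        br, bc = cy + mid_r * math.sin(theta), cx + mid_r * math.cos(theta)
        brad = rng.uniform(0.002, 0.008) * n
        shade = rng.uniform(0.6, 0.9)
        blotch = ring & (np.hypot(yy - br, xx - bc) <= brad)
        color = np.clip(np.array(pal.border) * shade, 0, 255).astype(np.uint8)
        if tuple(color) in (pal.white_colony, pal.red_sector):
            color = np.clip(color.astype(int) - 1, 0, 255).astype(np.uint8)
        img[blotch] = color

    count_mask = np.zeros((n, n), dtype=np.uint8)
    for col in layout:
        r0, c0 = col.center
        d = np.hypot(yy - r0, xx - c0)
        inside = d <= col.radius
        img[inside] = pal.white_colony
        if col.sectors:
            ang = _angle_deg(yy - r0, xx - c0)
            for start, end in col.sectors:
                img[inside & _in_interval(ang, start, end)] = pal.red_sector
        dot = d <= COUNT_MASK_RADIUS
        count_mask[dot] = min(255, COUNT_MASK_STEP * (len(col.sectors) + 1))

    # class mask by exact color identity on the clean render
    class_mask = np.zeros((n, n), dtype=np.uint8)
    class_mask[np.all(img == pal.white_colony, axis=-1)] = WHITE
    class_mask[np.all(img == pal.red_sector, axis=-1)] = RED

    clean = img.copy()
    if spec.noise_enabled:
        img = apply_poisson_noise(img, _stage_rng(spec, 2))

    return SyntheticPlate(
        image=img,
        class_mask=class_mask,
        count_mask=count_mask,
        layout=list(layout),
        clean_image=clean,
    )


def apply_poisson_noise(image: np.ndarray, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Replace each 8-bit channel value by a Poisson draw with that mean.

    Poisson shot noise introduces the slight per-pixel color variation seen
    in photographs; a clean value of 0 stays 0 exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    noisy = rng.poisson(image.astype(np.float64))
    return np.clip(noisy, 0, 255).astype(np.uint8)


def generate_plate(spec: PlateSpec) -> SyntheticPlate:
    return render_plate(spec, sample_layout(spec))


def generate_plates(spec: PlateSpec, n_images: int) -> list[SyntheticPlate]:
    """Generate ``n_images`` plates with per-image seeds derived from the spec."""
    out = []
    for i in range(n_images):
        s = replace(spec, rng_seed=(int(spec.rng_seed) * 10007 + i) % (2**31))
        out.append(generate_plate(s))
    return out


def layout_truth_label(colony: ColonyLayout) -> str:
    """Ground-truth phenotype label of one synthetic colony.

    No sectors -> all white -> "PSI+"; sectors covering the full circle ->
    all red -> "psi-"; otherwise sectored with label "S{k}".
    """
    if not colony.sectors:
        return "PSI+"
    total = sum((end - start) % 360.0 or 360.0 for start, end in colony.sectors)
    if total >= 360.0:
        return "psi-"
    return f"S{len(colony.sectors)}"


def write_plate(out_dir, index: int, plate: SyntheticPlate) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    masks.save_image(out_dir / f"plate_{index}.png", plate.image)
    masks.save_mask(out_dir / f"plate_{index}_class.png", plate.class_mask)
    masks.save_gray(out_dir / f"plate_{index}_count.png", plate.count_mask)
    records = [
        {
            "center": [colony.center[0], colony.center[1]],
            "radius": colony.radius,
            "sectors": [list(iv) for iv in colony.sectors],
        }
        for colony in plate.layout
    ]
    (out_dir / f"plate_{index}_layout.json").write_text(json.dumps(records, indent=1))


def load_layout(path) -> list[ColonyLayout]:
    records = json.loads(Path(path).read_text())
    return [
        ColonyLayout(
            center=(float(r["center"][0]), float(r["center"][1])),
            radius=float(r["radius"]),
            sectors=tuple((float(a), float(b)) for a, b in r["sectors"]),
        )
        for r in records
    ]
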