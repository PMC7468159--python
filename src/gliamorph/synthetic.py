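"""Synthetic fluorescence fields of branched glial cells with analytic ground truth.

The generator emulates single-channel 20x confocal fields (424 um square,
~0.18 mm^2) containing a handful of branched glial cells -- an elliptical
soma plus a tree of radiating processes -- rendered over a noisy background.
Every morphological quantity the measurement pipeline later estimates
(primary-branch count, branch-point count, total branch length, cell radius,
cell area, soma area, soma eccentricity, field density) is derivable from the
cell specification in closed form, so the ground truth never depends on the
raster, the random seed, or the noise level.

Coordinates are in micrometres with x along image columns and y along rows;
pixel (r, c) has its centre at ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "BranchSpec",
    "CellSpec",
    "CellGroundTruth",
    "FieldGroundTruth",
    "FieldImage",
    "CellRegime",
    "MICROGLIA_REGIME",
    "ASTROCYTE_REGIME",
    "DEFAULT_MUTANT_FACTORS",
    "render_cell",
    "render_field",
    "sample_cell_spec",
    "sample_field_specs",
    "make_group_dataset",
    "make_densitometry_table",
    "scaled_regime",
]


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class BranchSpec:
    """One straight process segment with optional daughter segments at its tip.

    ``turn`` is the direction change relative to the parent segment, in
    radians; for a primary branch (a tree root) it is the absolute direction
    in the field frame.  A node with two or more children is a bifurcation
    (a branch point); a single child is a mere kink in the polyline.
    """

    length: float
    turn: float = 0.0
    children: tuple["BranchSpec", ...] = ()

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"segment length must be > 0, got {self.length}")

    @property
    def n_segments(self) -> int:
        return 1 + sum(c.n_segments for c in self.children)

    @property
    def total_length(self) -> float:
        return self.length + sum(c.total_length for c in self.children)

    @property
    def n_bifurcations(self) -> int:
        own = 1 if len(self.children) >= 2 else 0
        return own + sum(c.n_bifurcations for c in self.children)


@dataclass(frozen=True)
class CellSpec:
    """Generative description of one glial cell.

    soma_center : (x, y) in um, field frame.
    soma_axes : (a, b) ellipse semi-axes in um, a >= b > 0.
    soma_angle : major-axis orientation, radians.
    branch_tree : one :class:`BranchSpec` per primary branch; the root
        ``turn`` is the absolute direction in which the primary leaves the
        soma boundary.
    process_width : full width of the rendered processes, um.
    intensity_* : arbitrary fluorescence units, soma > process > background.
    noise_sd : additive Gaussian noise sigma applied after blurring.
    psf_sigma : isotropic Gaussian point-spread sigma, um.
    """

    soma_center: tuple[float, float]
    soma_axes: tuple[float, float]
    soma_angle: float = 0.0
    branch_tree: tuple[BranchSpec, ...] = ()
    process_width: float = 1.5
    intensity_soma: float = 3000.0
    intensity_process: float = 1200.0
    intensity_background: float = 200.0
    noise_sd: float = 0.0
    psf_sigma: float = 0.3

    def __post_init__(self) -> None:
        a, b = self.soma_axes
        if not (a >= b > 0):
            raise ValueError(f"soma semi-axes must satisfy a >= b > 0, got {self.soma_axes}")
        if not (self.intensity_soma > self.intensity_process > self.intensity_background >= 0):
            raise ValueError("intensities must satisfy soma > process > background >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.process_width <= 0:
            raise ValueError("process_width must be > 0")

    # -- closed-form geometry ------------------------------------------------

    def boundary_point(self, direction: float) -> tuple[float, float]:
        """Point where a ray from the soma centre at ``direction`` meets the
        ellipse boundary."""
        a, b = self.soma_axes
        phi = direction - self.soma_angle
        r = a * b / math.hypot(b * math.cos(phi), a * math.sin(phi))
        cx, cy = self.soma_center
        return (cx + r * math.cos(direction), cy + r * math.sin(direction))

    def iter_segments(self) -> Iterator[tuple[tuple[float, float], tuple[float, float]]]:
        """Yield absolute (start, end) points of every process segment."""

        def walk(branch: BranchSpec, start: tuple[float, float], direction: float):
            direction = direction + branch.turn
            end = (
                start[0] + branch.length * math.cos(direction),
                start[1] + branch.length * math.sin(direction),
            )
            yield start, end
            for child in branch.children:
                yield from walk(child, end, direction)

        for primary in self.branch_tree:
            start = self.boundary_point(primary.turn)
            # root turn is absolute: feed direction 0 so turn applies directly
            yield from walk(replace(primary, turn=primary.turn), start, 0.0)

    # ground truth ----------------------------------------------------------

    @property
    def soma_area(self) -> float:
        a, b = self.soma_axes
        return math.pi * a * b

    @property
    def soma_eccentricity(self) -> float:
        a, b = self.soma_axes
        return math.sqrt(1.0 - (b / a) ** 2)

    @property
    def n_primary(self) -> int:
        return len(self.branch_tree)

    @property
    def n_branch_points(self) -> int:
        return sum(p.n_bifurcations for p in self.branch_tree)

    @property
    def total_length(self) -> float:
        return float(sum(p.total_length for p in self.branch_tree))

    @property
    def cell_radius(self) -> float:
        """Maximum reach from the soma centre: furthest process vertex, or the
        major semi-axis for a process-free cell."""
        cx, cy = self.soma_center
        r = self.soma_axes[0]
        for p0, p1 in self.iter_segments():
            r = max(r, math.hypot(p1[0] - cx, p1[1] - cy))
        return float(r)

    @property
    def cell_area(self) -> float:
        """Approximate footprint: soma ellipse plus process ribbons
        (overlap at junctions not corrected)."""
        return float(self.soma_area + self.total_length * self.process_width)

    def support_radius(self) -> float:
        """Radius of a disc around the soma centre guaranteed to contain the
        rendered signal (including process width and blur tails)."""
        return self.cell_radius + self.process_width / 2 + 3.0 * self.psf_sigma

    def ground_truth(self) -> "CellGroundTruth":
        return CellGroundTruth(
            soma_center=self.soma_center,
            n_primary=self.n_primary,
            n_branch_points=self.n_branch_points,
            total_length_um=self.total_length,
            cell_radius_um=self.cell_radius,
            cell_area_um2=self.cell_area,
            soma_area_um2=self.soma_area,
            soma_eccentricity=self.soma_eccentricity,
        )


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass(frozen=True)
class CellGroundTruth:
    soma_center: tuple[float, float]
    n_primary: int
    n_branch_points: int
    total_length_um: float
    cell_radius_um: float
    cell_area_um2: float
    soma_area_um2: float
    soma_eccentricity: float

    def as_dict(self) -> dict:
        d = {
            "soma_x_um": self.soma_center[0],
            "soma_y_um": self.soma_center[1],
            "n_primary_branches": self.n_primary,
            "n_branch_points": self.n_branch_points,
            "total_branch_length_um": self.total_length_um,
            "cell_radius_um": self.cell_radius_um,
            "cell_area_um2": self.cell_area_um2,
            "soma_area_um2": self.soma_area_um2,
            "soma_eccentricity": self.soma_eccentricity,
        }
        return d


@dataclass(frozen=True)
class FieldGroundTruth:
    cells: tuple[CellGroundTruth, ...]
    field_area_mm2: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def density_cells_per_mm2(self) -> float:
        return self.n_cells / self.field_area_mm2

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(cell=i, **c.as_dict()) for i, c in enumerate(self.cells)]
        return pd.DataFrame(
            rows,
            columns=[
                "cell", "soma_x_um", "soma_y_um", "n_primary_branches",
                "n_branch_points", "total_branch_length_um", "cell_radius_um",
                "cell_area_um2", "soma_area_um2", "soma_eccentricity",
            ],
        )


@dataclass
class FieldImage:
    """A calibrated single-channel 2-D intensity grid."""

    pixels: np.ndarray
    pixel_size: float
    channel: str = "IBA1-like"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("intensities must be finite and >= 0")

    @property
    def field_area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * self.pixel_size**2 / 1e6


# ---------------------------------------------------------------------------
# rasterization


def _paint_ellipse(canvas: np.ndarray, pixel_size: float, center: tuple[float, float],
                   axes: tuple[float, float], angle: float, value: float) -> None:
    a, b = axes
    cx, cy = center
    h, w = canvas.shape
    r_ext = a / pixel_size + 1
    r0 = max(int(cy / pixel_size - 0.5 - r_ext), 0)
    r1 = min(int(cy / pixel_size - 0.5 + r_ext) + 2, h)
    c0 = max(int(cx / pixel_size - 0.5 - r_ext), 0)
    c1 = min(int(cx / pixel_size - 0.5 + r_ext) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x = (cc + 0.5) * pixel_size - cx
    y = (rr + 0.5) * pixel_size - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    patch = canvas[r0:r1, c0:c1]
    patch[inside] = np.maximum(patch[inside], value)


def _paint_capsule(canvas: np.ndarray, pixel_size: float, p0: tuple[float, float],
                   p1: tuple[float, float], width: float, value: float) -> None:
    """Paint all pixels whose centre lies within width/2 of segment p0-p1."""
    h, w = canvas.shape
    half = width / 2
    xmin = min(p0[0], p1[0]) - half
    xmax = max(p0[0], p1[0]) + half
    ymin = min(p0[1], p1[1]) - half
    ymax = max(p0[1], p1[1]) + half
    r0 = max(int(ymin / pixel_size - 0.5) - 1, 0)
    r1 = min(int(ymax / pixel_size - 0.5) + 3, h)
    c0 = max(int(xmin / pixel_size - 0.5) - 1, 0)
    c1 = min(int(xmax / pixel_size - 0.5) + 3, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x = (cc + 0.5) * pixel_size
    y = (rr + 0.5) * pixel_size
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    t = ((x - p0[0]) * dx + (y - p0[1]) * dy) / seg2
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(x - (p0[0] + t * dx), y - (p0[1] + t * dy))
    inside = dist <= half
    patch = canvas[r0:r1, c0:c1]
    patch[inside] = np.maximum(patch[inside], value)


def _paint_cell(canvas: np.ndarray, pixel_size: float, spec: CellSpec) -> None:
    cx, cy = spec.soma_center
    for p0, p1 in spec.iter_segments():
        # pull the primary start ~1 um into the soma so raster support is
        # connected; the inset lies inside the soma and is not counted in the
        # ground-truth length
        d = math.hypot(p0[0] - cx, p0[1] - cy)
        if d > 0:
            inset = min(1.0, d)
            p0 = (p0[0] - inset * (p0[0] - cx) / d, p0[1] - inset * (p0[1] - cy) / d)
        _paint_capsule(canvas, pixel_size, p0, p1, spec.process_width, spec.intensity_process)
    _paint_ellipse(canvas, pixel_size, spec.soma_center, spec.soma_axes,
                   spec.soma_angle, spec.intensity_soma)


def _finish(canvas: np.ndarray, pixel_size: float, psf_sigma: float, noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    if psf_sigma > 0:
        canvas = gaussian_filter(canvas, sigma=psf_sigma / pixel_size)
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, size=canvas.shape)
    return np.clip(canvas, 0.0, None)


def render_cell(spec: CellSpec, pixel_size: float, rng_seed: int,
                patch_shape: tuple[int, int] | None = None,
                channel: str = "IBA1-like") -> tuple[FieldImage, CellGroundTruth]:
    """Rasterize one cell into its own patch.

    The patch is sized to the cell's support unless ``patch_shape`` is given,
    in which case a cell extending beyond the patch is rejected with a
    ``ValueError`` (no silent clipping).  Ground truth is computed from the
    spec in closed form, never from the raster.
    """
    R = spec.support_radius()
    cx, cy = spec.soma_center
    if patch_shape is None:
        side = int(math.ceil(2 * (R + 2 * pixel_size) / pixel_size))
        patch_shape = (side, side)
        # re-centre the cell in its patch
        offset = (side * pixel_size / 2 - cx, side * pixel_size / 2 - cy)
        spec_local = replace(spec, soma_center=(cx + offset[0], cy + offset[1]))
    else:
        spec_local = spec
    h, w = patch_shape
    cx_l, cy_l = spec_local.soma_center
    if (cx_l - R < 0 or cy_l - R < 0 or cx_l + R > w * pixel_size
            or cy_l + R > h * pixel_size):
        raise ValueError(
            f"cell at ({cx:.1f}, {cy:.1f}) um with support radius {R:.1f} um "
            f"extends beyond the {h}x{w} patch")
    canvas = np.full(patch_shape, spec.intensity_background, dtype=np.float64)
    _paint_cell(canvas, pixel_size, spec_local)
    rng = np.random.default_rng(rng_seed)
    canvas = _finish(canvas, pixel_size, spec.psf_sigma, spec.noise_sd, rng)
    return FieldImage(canvas, pixel_size, channel), spec.ground_truth()


def render_field(specs: Sequence[CellSpec], field_side: float, pixel_size: float,
                 rng_seed: int, allow_overlap: bool = False,
                 channel: str = "IBA1-like") -> tuple[FieldImage, FieldGroundTruth]:
    """Rasterize a square field containing the given cells.

    Deterministic for a fixed seed.  Cells must lie fully inside the field and
    must be pairwise non-overlapping (bounding-disc test) unless
    ``allow_overlap`` is set.  Background, noise and PSF must be uniform
    across the field's specs.
    """
    n_px = int(round(field_side / pixel_size))
    if specs:
        ref = specs[0]
        for i, s in enumerate(specs):
            if (s.intensity_background != ref.intensity_background
                    or s.noise_sd != ref.noise_sd or s.psf_sigma != ref.psf_sigma):
                raise ValueError(
                    f"cell {i}: background/noise/psf must be uniform within a field")
    radii = [s.support_radius() for s in specs]
    for i, (s, R) in enumerate(zip(specs, radii)):
        cx, cy = s.soma_center
        if cx - R < 0 or cy - R < 0 or cx + R > field_side or cy + R > field_side:
            raise ValueError(
                f"cell {i} at ({cx:.1f}, {cy:.1f}) um with support radius "
                f"{R:.1f} um extends beyond the {field_side} um field")
    if not allow_overlap:
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                d = math.dist(specs[i].soma_center, specs[j].soma_center)
                if d < radii[i] + radii[j]:
                    raise ValueError(
                        f"cells {i} and {j} overlap (centre distance {d:.1f} um "
                        f"< {radii[i] + radii[j]:.1f} um)")
    bg = specs[0].intensity_background if specs else 0.0
    psf = specs[0].psf_sigma if specs else 0.0
    noise = specs[0].noise_sd if specs else 0.0
    canvas = np.full((n_px, n_px), bg, dtype=np.float64)
    for s in specs:
        _paint_cell(canvas, pixel_size, s)
    rng = np.random.default_rng(rng_seed)
    canvas = _finish(canvas, pixel_size, psf, noise, rng)
    image = FieldImage(canvas, pixel_size, channel)
    truth = FieldGroundTruth(tuple(s.ground_truth() for s in specs),
                             field_area_mm2=image.field_area_mm2)
    return image, truth


# ---------------------------------------------------------------------------
# regime sampling


@dataclass(frozen=True)
class CellRegime:
    """Uniform sampling ranges for cell morphology, set to the published
    hippocampal regimes (soma ~48-57 um^2, eccentricity 0.79-0.87, 4-6 primary
    branches, 3-6 branch points, total branch length ~97-204 um)."""

    soma_area_um2: tuple[float, float] = (48.0, 57.0)
    soma_eccentricity: tuple[float, float] = (0.79, 0.87)
    n_primary: tuple[int, int] = (4, 6)
    n_branch_points: tuple[int, int] = (3, 6)
    total_length_um: tuple[float, float] = (97.0, 204.0)
    cells_per_field: tuple[int, int] = (4, 12)
    process_width: float = 1.5
    intensity_soma: float = 3000.0
    intensity_process: float = 1200.0
    intensity_background: float = 200.0
    noise_sd: float = 0.0
    psf_sigma: float = 0.3

    @property
    def snr(self) -> float:
        """Process contrast over noise sigma (inf for noiseless)."""
        contrast = self.intensity_process - self.intensity_background
        return math.inf if self.noise_sd == 0 else contrast / self.noise_sd


MICROGLIA_REGIME = CellRegime(
    soma_area_um2=(45.0, 55.0), soma_eccentricity=(0.75, 0.83),
    n_primary=(3, 5), n_branch_points=(3, 6), total_length_um=(120.0, 185.0),
    cells_per_field=(4, 8),
)

ASTROCYTE_REGIME = CellRegime(
    soma_area_um2=(48.0, 57.0), soma_eccentricity=(0.79, 0.87),
    n_primary=(4, 6), n_branch_points=(4, 7), total_length_um=(140.0, 204.0),
    cells_per_field=(8, 14),
)

#: Default mutant-vs-WT effect: the published dentate-gyrus astrocyte
#: total-branch-length ratio 96.8/167 and branch-point ratio 2.87/5.84.
DEFAULT_MUTANT_FACTORS = {
    "total_length_um": 96.8 / 167.0,
    "n_branch_points": 2.87 / 5.84,
}

_MIN_SEGMENT_UM = 6.0


def scaled_regime(regime: CellRegime, factors: dict[str, float]) -> CellRegime:
    """Scale selected range fields of a regime by multiplicative factors.

    Supported keys: soma_area_um2, soma_eccentricity, total_length_um,
    n_primary, n_branch_points, cells_per_field (density factor).
    """
    updates: dict = {}
    for key, f in factors.items():
        lo, hi = getattr(regime, key)
        if isinstance(lo, int):
            updates[key] = (max(0, int(round(lo * f))), max(0, int(round(hi * f))))
        else:
            updates[key] = (lo * f, hi * f)
    return replace(regime, **updates)


def _build_branch(lengths: list[float], turns_rng: np.random.Generator,
                  n_bp: int) -> BranchSpec:
    """Build one primary-branch tree consuming lengths from the list."""

    def child(depth: int, bp_left: list[int], sign: float) -> BranchSpec:
        turn = sign * turns_rng.uniform(0.35, 0.6)
        length = lengths.pop()
        if depth < 2 and bp_left[0] > 0:
            bp_left[0] -= 1
            kids = (child(depth + 1, bp_left, 1.0), child(depth + 1, bp_left, -1.0))
            return BranchSpec(length, turn, kids)
        return BranchSpec(length, turn)

    bp_left = [n_bp]
    length = lengths.pop()
    if bp_left[0] > 0:
        bp_left[0] -= 1
        kids = (child(1, bp_left, 1.0), child(1, bp_left, -1.0))
        return BranchSpec(length, 0.0, kids)
    return BranchSpec(length, 0.0)


def _segment_pair_distance(s1, s2) -> float:
    """Minimum distance between two 2-D segments."""
    (p0, p1), (q0, q1) = s1, s2

    def cross(ax, ay, bx, by):
        return ax * by - ay * bx

    def point_seg(pt, a, b):
        abx, aby = b[0] - a[0], b[1] - a[1]
        denom = max(abx * abx + aby * aby, 1e-12)
        t = ((pt[0] - a[0]) * abx + (pt[1] - a[1]) * aby) / denom
        t = min(max(t, 0.0), 1.0)
        return math.hypot(pt[0] - a[0] - t * abx, pt[1] - a[1] - t * aby)

    ux, uy = p1[0] - p0[0], p1[1] - p0[1]
    vx, vy = q1[0] - q0[0], q1[1] - q0[1]
    d1 = cross(ux, uy, q0[0] - p0[0], q0[1] - p0[1])
    d2 = cross(ux, uy, q1[0] - p0[0], q1[1] - p0[1])
    d3 = cross(vx, vy, p0[0] - q0[0], p0[1] - q0[1])
    d4 = cross(vx, vy, p1[0] - q0[0], p1[1] - q0[1])
    if d1 * d2 < 0 and d3 * d4 < 0:
        return 0.0
    return min(point_seg(q0, p0, p1), point_seg(q1, p0, p1),
               point_seg(p0, q0, q1), point_seg(p1, q0, q1))


def _self_intersects(spec: CellSpec, clearance: float) -> bool:
    segs = list(spec.iter_segments())
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b = segs[i], segs[j]
            # ignore segments sharing an endpoint (parent/child, siblings)
            shared = any(math.dist(pa, pb) < 1e-9 for pa in a for pb in b)
            if shared:
                continue
            if _segment_pair_distance(a, b) < clearance:
                return True
    return False


def sample_cell_spec(rng: np.random.Generator, regime: CellRegime = CellRegime(),
                     center: tuple[float, float] = (0.0, 0.0),
                     max_tries: int = 100) -> CellSpec:
    """Draw one cell specification from a regime.

    Branch-point counts are capped so that every segment stays above
    ~6 um after scaling to the target total length, keeping real branches
    well clear of the default 2 um spur-pruning length.  Candidate trees
    whose non-adjacent segments pass closer than ~2.5 um are resampled so
    that distinct processes never merge in the raster.
    """
    for _ in range(max_tries):
        area = rng.uniform(*regime.soma_area_um2)
        ecc = rng.uniform(*regime.soma_eccentricity)
        q = math.sqrt(1.0 - ecc**2)  # b/a
        a = math.sqrt(area / (math.pi * q))
        b = a * q
        n_primary = int(rng.integers(regime.n_primary[0], regime.n_primary[1] + 1))
        total = rng.uniform(*regime.total_length_um)
        bp_cap = max(0, int((total / (1.25 * _MIN_SEGMENT_UM) - n_primary) // 2))
        bp_lo = min(regime.n_branch_points[0], bp_cap)
        bp_hi = min(regime.n_branch_points[1], bp_cap)
        n_bp = int(rng.integers(bp_lo, bp_hi + 1)) if bp_hi > 0 else 0
        # distribute bifurcations over primaries (max 3 each: depth-2 trees)
        per_primary = [0] * n_primary
        for _k in range(n_bp):
            open_idx = [i for i, v in enumerate(per_primary) if v < 3]
            per_primary[int(rng.choice(open_idx))] += 1
        n_seg = n_primary + 2 * n_bp
        raw = rng.uniform(0.75, 1.25, size=n_seg)
        lengths = list(raw * (total / raw.sum()))
        if min(lengths) < 0.8 * _MIN_SEGMENT_UM:
            continue
        soma_angle = rng.uniform(0, 2 * math.pi)
        sector = 2 * math.pi / n_primary
        base = rng.uniform(0, 2 * math.pi)
        tree = []
        for k in range(n_primary):
            angle = base + k * sector + rng.uniform(-0.15, 0.15) * sector
            primary = _build_branch(lengths, rng, per_primary[k])
            tree.append(replace(primary, turn=angle % (2 * math.pi)))
        assert not lengths
        spec = CellSpec(
            soma_center=center, soma_axes=(a, b), soma_angle=soma_angle,
            branch_tree=tuple(tree), process_width=regime.process_width,
            intensity_soma=regime.intensity_soma,
            intensity_process=regime.intensity_process,
            intensity_background=regime.intensity_background,
            noise_sd=regime.noise_sd, psf_sigma=regime.psf_sigma,
        )
        if not _self_intersects(spec, clearance=1.7 * regime.process_width):
            # fix total length exactly (jitter + resampling preserve it already)
            return spec
    raise RuntimeError("failed to sample a non-self-intersecting cell spec")


def sample_field_specs(rng: np.random.Generator, n_cells: int, field_side: float,
                       regime: CellRegime = CellRegime(),
                       max_tries: int = 50) -> list[CellSpec]:
    """Sample ``n_cells`` non-overlapping cells placed on a jittered grid.

    Raises ``ValueError`` when the field cannot hold that many cells of the
    regime's size without overlap.
    """
    last_reason = "no attempt made"
    for _ in range(max_tries):
        cells = [sample_cell_spec(rng, regime) for _ in range(n_cells)]
        rmax = max((c.support_radius() for c in cells), default=10.0)
        margin = rmax + 2.0
        usable = field_side - 2 * margin
        pitch = 2 * rmax + 4.0
        k = int(usable // pitch) + 1
        if k * k < n_cells:
            last_reason = (
                f"cannot place {n_cells} cells of support radius {rmax:.1f} um "
                f"in a {field_side} um field without overlap")
            continue  # resample: the regime may yield smaller cells
        sites = [(margin + i * usable / max(k - 1, 1), margin + j * usable / max(k - 1, 1))
                 for i in range(k) for j in range(k)]
        chosen = rng.choice(len(sites), size=n_cells, replace=False)
        # keep jitter small enough that edge sites stay inside the field
        jitter = min(max((usable / max(k - 1, 1) - pitch) / 2, 0.0), 1.5)
        placed = []
        for cell, si in zip(cells, chosen):
            x = sites[si][0] + rng.uniform(-jitter, jitter)
            y = sites[si][1] + rng.uniform(-jitter, jitter)
            placed.append(replace(cell, soma_center=(x, y)))
        # verify the pairwise guarantee (jitter keeps it by construction)
        ok = all(
            math.dist(placed[i].soma_center, placed[j].soma_center)
            >= placed[i].support_radius() + placed[j].support_radius()
            for i in range(n_cells) for j in range(i + 1, n_cells))
        if ok:
            return placed
        last_reason = "jittered placement violated the pairwise clearance"
    raise ValueError(f"failed to place non-overlapping cells: {last_reason}")


# ---------------------------------------------------------------------------
# grouped datasets


def make_group_dataset(wt_regime: CellRegime = ASTROCYTE_REGIME,
                       mutant_regime: CellRegime | None = None,
                       n_animals: int = 5, fields_per_animal: int = 1,
                       rng_seed: int = 0, field_side: float = 424.0,
                       pixel_size: float = 0.415, render: bool = True,
                       region: str = "DG",
                       ) -> tuple[pd.DataFrame, dict[str, list[list[FieldImage | None]]]]:
    """Simulate a two-genotype study with the animal as sampling unit.

    Returns ``(truth_table, images)`` where ``truth_table`` has one row per
    planted cell (columns: genotype, animal_id, region, field, cell and the
    per-cell morphology truth) plus the per-field density, and ``images`` maps
    genotype -> animals -> fields (``None`` when ``render=False``).

    The mutant regime defaults to the WT regime scaled by
    :data:`DEFAULT_MUTANT_FACTORS` (total branch length x0.58, branch points
    x0.49, the published dentate-gyrus astrocyte effect).
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals per group")
    if fields_per_animal < 1:
        raise ValueError("fields_per_animal must be >= 1")
    if mutant_regime is None:
        mutant_regime = scaled_regime(wt_regime, DEFAULT_MUTANT_FACTORS)
    rng = np.random.default_rng(rng_seed)
    rows = []
    images: dict[str, list[list[FieldImage | None]]] = {}
    for genotype, regime in (("WT", wt_regime), ("NL3", mutant_regime)):
        images[genotype] = []
        for animal in range(n_animals):
            animal_id = f"{genotype}_{animal + 1:02d}"
            per_field: list[FieldImage | None] = []
            for f in range(fields_per_animal):
                lo, hi = regime.cells_per_field
                n_cells = int(rng.integers(lo, hi + 1))
                specs = sample_field_specs(rng, n_cells, field_side, regime)
                if render:
                    img, truth = render_field(
                        specs, field_side, pixel_size,
                        rng_seed=int(rng.integers(0, 2**31 - 1)))
                else:
                    area = (round(field_side / pixel_size)) ** 2 * pixel_size**2 / 1e6
                    truth = FieldGroundTruth(
                        tuple(s.ground_truth() for s in specs), field_area_mm2=area)
                    img = None
                per_field.append(img)
                for i, cell in enumerate(truth.cells):
                    rows.append(dict(
                        genotype=genotype, animal_id=animal_id, region=region,
                        field=f, cell=i,
                        density_cells_per_mm2=truth.density_cells_per_mm2,
                        **cell.as_dict()))
            images[genotype].append(per_field)
    return pd.DataFrame(rows), images


def make_densitometry_table(rng_seed: int = 0, effect: float = 0.67,
                            target: str = "SNAP-25", region: str = "cortex",
                            n_wt: int = 6, n_mut: int = 6, n_blots: int = 1,
                            lane_cv: float = 0.15) -> pd.DataFrame:
    """Simulate a densitometry band-intensity table for one target.

    Mutant lanes carry a multiplicative effect on the target/actin ratio
    (default 0.67, the published cortical SNAP-25 level relative to WT).
    Lane-to-lane variation is log-normal with coefficient of variation
    ``lane_cv`` on both the actin intensity and the ratio.
    """
    rng = np.random.default_rng(rng_seed)
    sigma = math.sqrt(math.log(1 + lane_cv**2))
    rows = []
    for blot in range(n_blots):
        base_ratio = rng.uniform(0.6, 1.6)
        lane = 0
        for genotype, n, eff in (("WT", n_wt, 1.0), ("NL3", n_mut, effect)):
            for _ in range(n):
                actin = rng.lognormal(math.log(1e4), sigma)
                ratio = base_ratio * eff * rng.lognormal(-0.5 * sigma**2, sigma)
                rows.append(dict(
                    blot_id=f"blot{blot + 1}", lane=f"blot{blot + 1}_lane{lane + 1}",
                    genotype=genotype, region=region, target=target,
                    target_intensity=ratio * actin, actin_intensity=actin))
                lane += 1
    return pd.DataFrame(rows)
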