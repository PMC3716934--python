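"""Transect planning and sonar coverage masks.

A downward-looking sonar with cone apex angle ``alpha`` ensonifies, at depth
``k``, a band of width ``2 k tan(alpha/2)`` beneath the track line.  A survey
is a lawn-mower pattern of parallel transects at spacing ``Tm``; the coverage
mask ``Lf`` marks the grid cells swept by the beam.

The practical spacing rule ``Tm = 9 k tan(alpha/2)`` gives the largest
transect spacing for which the ensonified volume fraction stays near 10%; it
is implemented exactly as stated, without re-deriving the constant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ParameterError

__all__ = [
    "BeamGeometry",
    "TransectPlan",
    "CoverageMask",
    "transect_spacing",
    "footprint_width",
    "plan_transects",
    "coverage_mask_2d",
    "coverage_mask_3d",
]


def _check_alpha(alpha_deg: float) -> None:
    if not 0.0 < alpha_deg < 180.0:
        raise ParameterError(f"cone angle must be in (0, 180) degrees, got {alpha_deg}")


def footprint_width(alpha_deg: float, depth_m: float) -> float:
    """Width in meters of the ensonified band at ``depth_m`` for cone angle ``alpha_deg``.

    ``w = 2 * depth * tan(alpha/2)``; zero at the surface (cone apex).
    """
    _check_alpha(alpha_deg)
    if depth_m < 0:
        raise ParameterError("depth must be non-negative")
    return 2.0 * depth_m * math.tan(math.radians(alpha_deg) / 2.0)


def transect_spacing(alpha_deg: float, depth_m: float) -> float:
    """Maximum transect spacing ``Tm = 9 * depth * tan(alpha/2)`` in meters.

    The rule targets roughly 10% ensonified volume; e.g. for a 30-degree cone
    it gives 0.24, 2.4 and 7.2 m at depths 0.1, 1 and 3 m.
    """
    _check_alpha(alpha_deg)
    if depth_m < 0:
        raise ParameterError("depth must be non-negative")
    return 9.0 * depth_m * math.tan(math.radians(alpha_deg) / 2.0)


@dataclass(frozen=True)
class BeamGeometry:
    """Sonar beam cone geometry (apex angle in degrees)."""

    alpha_deg: float = 30.0

    def __post_init__(self) -> None:
        _check_alpha(self.alpha_deg)

    def footprint_width_m(self, depth_m: float) -> float:
        return footprint_width(self.alpha_deg, depth_m)


@dataclass(frozen=True)
class TransectPlan:
    """Parallel track lines across a grid.

    ``spacing`` and ``offset`` are in cells; track centre lines sit at
    ``offset + i * spacing`` for ``i in 0..n_tracks-1`` along the orientation
    axis.  ``footprint_cells`` is the swath width of one track in cells (at
    the working depth for 2D masks).
    """

    spacing: float
    offset: float
    n_tracks: int
    footprint_cells: int
    orientation: str = "columns"  # bands sweep whole rows of constant column
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        if self.n_tracks < 1:
            raise ParameterError("n_tracks must be >= 1")
        if self.orientation not in ("columns", "rows"):
            raise ParameterError("orientation must be 'columns' or 'rows'")

    @property
    def centers(self) -> np.ndarray:
        return self.offset + self.spacing * np.arange(self.n_tracks)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TransectPlan":
        return cls(**json.loads(text))


@dataclass
class CoverageMask:
    """Binary sonar-footprint grid ``Lf``, same shape as its occupancy grid."""

    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.cells.shape

    @property
    def covered_count(self) -> int:
        return int(self.cells.sum())


def _band_axis(extent: int, centers: np.ndarray, width_cells: int) -> np.ndarray:
    """1D boolean coverage along the cross-track axis: width-``width_cells``
    bands centred on each track line, clipped at the grid edge."""
    covered = np.zeros(extent, dtype=bool)
    if width_cells <= 0:
        return covered
    for c in centers:
        start = int(math.floor(c - width_cells / 2.0 + 0.5))
        covered[max(0, start):min(extent, start + width_cells)] = True
    return covered


def plan_transects(
    extent_cells: int,
    target_pf_percent: float,
    footprint_cells: float,
    orientation: str = "columns",
) -> TransectPlan:
    """Choose a number of equally spaced tracks realizing ``target_pf_percent`` coverage.

    The first track sits at ``spacing/2`` from the edge so bands are
    symmetric.  The track count is the rounding of
    ``target * extent / (100 * width)`` that brings the realized coverage
    closest to the target; when the footprint is at least as wide as the
    grid a single full-width track is returned, flagged degenerate.
    """
    if not 0.0 < target_pf_percent <= 100.0:
        raise ParameterError("target coverage must be in (0, 100] percent")
    if footprint_cells < 1:
        raise ParameterError("footprint must be at least one cell")
    w = int(round(footprint_cells))
    if w >= extent_cells:
        return TransectPlan(
            spacing=float(extent_cells), offset=extent_cells / 2.0, n_tracks=1,
            footprint_cells=w, orientation=orientation, degenerate=True,
        )
    ideal = target_pf_percent * extent_cells / (100.0 * w)
    best = None
    for n in {max(1, math.floor(ideal)), max(1, math.ceil(ideal))}:
        spacing = extent_cells / n
        covered = _band_axis(extent_cells, spacing / 2.0 + spacing * np.arange(n), w)
        realized = 100.0 * covered.sum() / extent_cells
        miss = abs(realized - target_pf_percent)
        if best is None or miss < best[0] or (miss == best[0] and n < best[1]):
            best = (miss, n, spacing)
    _, n, spacing = best
    return TransectPlan(
        spacing=spacing, offset=spacing / 2.0, n_tracks=n,
        footprint_cells=w, orientation=orientation,
    )


def coverage_mask_2d(plan: TransectPlan, M: int, N: int) -> CoverageMask:
    """2D coverage mask: the union of axis-parallel bands of the plan's footprint."""
    extent = N if plan.orientation == "columns" else M
    covered = _band_axis(extent, plan.centers, plan.footprint_cells)
    cells = np.zeros((M, N), dtype=bool)
    if plan.orientation == "columns":
        cells[:, covered] = True
    else:
        cells[covered, :] = True
    return CoverageMask(cells)


def coverage_mask_3d(
    plan: TransectPlan,
    M: int,
    N: int,
    K: int,
    beam: BeamGeometry,
    max_depth_m: float,
    cell_size_m: float = 1.0,
) -> CoverageMask:
    """3D coverage mask of the beam cone swept along the plan's tracks.

    Depth layer ``k`` (0-based) maps to physical depth ``k * max_depth_m / K``;
    the band width at that layer is the cone footprint converted to cells
    (nearest cell, ties away from the track line).  Layer 0 has width 0 (cone
    apex) and is empty; band width is non-decreasing with depth.
    """
    if max_depth_m <= 0:
        raise ParameterError("max_depth_m must be positive")
    if cell_size_m <= 0:
        raise ParameterError("cell_size_m must be positive")
    extent = N if plan.orientation == "columns" else M
    cells = np.zeros((M, N, K), dtype=bool)
    for k in range(K):
        depth = k * max_depth_m / K
        w = int(math.floor(beam.footprint_width_m(depth) / cell_size_m + 0.5))
        if w <= 0:
            continue
        covered = _band_axis(extent, plan.centers, w)
        if plan.orientation == "columns":
            cells[:, covered, k] = True
        else:
            cells[covered, :, k] = True
    return CoverageMask(cells)
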