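"""Coverage-error statistics for paired occupancy grids and coverage masks.

Notation: ``Lo`` is the binary fish-occupancy grid, ``Lf`` the binary
coverage mask and ``Ls = Lo * Lf`` the fish actually ensonified.  All
percentages are on the 0-100 scale.

* ``delta_f``: percentage of fish inside the covered region (detected-fish
  fraction).
* ``p_f`` / ``p_fs``: covered area (2D) / volume (3D) fraction.
* ``delta_p`` / ``delta_ps``: |detected-fish fraction - coverage fraction|,
  the sampling error of treating coverage as detection.
* ``estimate_total``: density extrapolation of the detected count to the
  whole grid; ``delta_pa`` is its relative error against the true count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InputError, UndefinedStatisticError
from .reservoir import OccupancyGrid
from .survey import CoverageMask

__all__ = [
    "CoverageErrorReport",
    "delta_f",
    "p_f",
    "delta_p",
    "p_fs",
    "delta_ps",
    "estimate_total",
    "delta_pa",
    "relative_count_error",
    "coverage_report_2d",
    "coverage_report_3d",
]


def _cells(x) -> np.ndarray:
    if isinstance(x, (OccupancyGrid, CoverageMask)):
        return x.cells
    return np.asarray(x).astype(bool)


def _pair(lo, lf, ndim: int) -> tuple[np.ndarray, np.ndarray]:
    lo, lf = _cells(lo), _cells(lf)
    if lo.shape != lf.shape:
        raise InputError(f"shape mismatch: grid {lo.shape} vs mask {lf.shape}")
    if lo.ndim != ndim:
        raise InputError(f"expected {ndim}D arrays, got {lo.ndim}D")
    return lo, lf


def delta_f(lo, lf) -> float:
    """Percentage of fish inside the coverage mask: ``100 * sum(Ls) / sum(Lo)``."""
    lo, lf = _pair(lo, lf, 2)
    fish = np.count_nonzero(lo)
    if fish == 0:
        raise UndefinedStatisticError("delta_f is undefined for an empty grid (no fish)")
    return 100.0 * np.count_nonzero(lo & lf) / fish


def p_f(lf) -> float:
    """Covered-area fraction of a 2D mask: ``100 * sum(Lf) / (M*N)``."""
    lf = _cells(lf)
    return 100.0 * np.count_nonzero(lf) / lf.size


def delta_p(lo, lf) -> float:
    """2D coverage error ``|delta_f - p_f|``; zero under full coverage or uniform fish."""
    return abs(delta_f(lo, lf) - p_f(lf))


def p_fs(lf3) -> float:
    """Covered-volume fraction of a 3D mask: ``100 * sum(Lf) / (M*N*K)``."""
    lf3 = _cells(lf3)
    if lf3.ndim != 3:
        raise InputError("p_fs expects a 3D mask")
    return 100.0 * np.count_nonzero(lf3) / lf3.size


def delta_ps(lo3, lf3, as_printed: bool = False) -> float:
    """3D coverage error, ``|100*sum(Ls)/sum(Lo) - p_fs|``.

    With ``as_printed=True`` the first term sums the coverage mask itself
    instead of the detected fish (``100*sum(Lf)/sum(Lo)``), a published
    variant retained for auditability; it is independent of where the fish
    actually are and is not used anywhere else in the package.
    """
    lo3, lf3 = _pair(lo3, lf3, 3)
    fish = np.count_nonzero(lo3)
    if fish == 0:
        raise UndefinedStatisticError("delta_ps is undefined for an empty grid")
    numer = np.count_nonzero(lf3) if as_printed else np.count_nonzero(lo3 & lf3)
    return abs(100.0 * numer / fish - p_fs(lf3))


def estimate_total(lo3, lf3) -> float:
    """Extrapolated total count: detected fish scaled by the inverse covered fraction.

    ``sum(Ls) * (M*N*K) / sum(Lf)``; exact under full coverage, unbiased for
    uniformly placed fish.
    """
    lo3, lf3 = _pair(lo3, lf3, 3)
    covered = np.count_nonzero(lf3)
    if covered == 0:
        raise UndefinedStatisticError("estimate_total requires a non-empty mask")
    return np.count_nonzero(lo3 & lf3) * lo3.size / covered


def delta_pa(lo3, lf3) -> float:
    """Relative error (%) of the extrapolated count against the true fish count."""
    lo3, lf3 = _pair(lo3, lf3, 3)
    fish = np.count_nonzero(lo3)
    if fish == 0:
        raise UndefinedStatisticError("delta_pa is undefined for an empty grid")
    return 100.0 * abs(estimate_total(lo3, lf3) - fish) / fish


def relative_count_error(estimated: float, reference: float,
                         rounded: bool = True) -> float:
    """Relative counting error ``100*|estimated - reference|/reference`` in percent.

    By default rounded half-up to the nearest integer percent, the convention
    used when comparing sonar counts against complete-catch reference counts.
    """
    if reference <= 0:
        raise UndefinedStatisticError("relative_count_error requires reference > 0")
    err = 100.0 * abs(estimated - reference) / reference
    if rounded:
        return float(math.floor(err + 0.5))
    return err


@dataclass
class CoverageErrorReport:
    """All coverage-error statistics for one grid/mask pair (2D, 3D or both)."""

    detected_count: int
    fish_count: int
    delta_f: float | None = None
    p_f: float | None = None
    delta_p: float | None = None
    p_fs: float | None = None
    delta_ps: float | None = None
    delta_pa: float | None = None
    estimated_count: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def coverage_report_2d(lo, lf) -> CoverageErrorReport:
    lo_, lf_ = _pair(lo, lf, 2)
    return CoverageErrorReport(
        detected_count=int(np.count_nonzero(lo_ & lf_)),
        fish_count=int(np.count_nonzero(lo_)),
        delta_f=delta_f(lo, lf),
        p_f=p_f(lf),
        delta_p=delta_p(lo, lf),
    )


def coverage_report_3d(lo3, lf3) -> CoverageErrorReport:
    lo_, lf_ = _pair(lo3, lf3, 3)
    return CoverageErrorReport(
        detected_count=int(np.count_nonzero(lo_ & lf_)),
        fish_count=int(np.count_nonzero(lo_)),
        p_fs=p_fs(lf3),
        delta_ps=delta_ps(lo3, lf3),
        delta_pa=delta_pa(lo3, lf3),
        estimated_count=estimate_total(lo3, lf3),
    )
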