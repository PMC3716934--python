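"""Readers and writers for the formats the package touches.

* Occupancy grids: binary PGM (P5) images plus a JSON sidecar with the grid
  dimensions and cluster spec; 3D grids are stored as depth slices stacked
  vertically.
* Echograms: 8-bit grayscale PNG or PGM plus a JSON metadata sidecar
  (range, surface row, bottom profile, GPS fixes, ping times) and a CSV
  ground-truth table.
* Detection tables: CSV with fixed 6-decimal float formatting so equal
  tables round-trip to identical bytes.
* GPS: a minimal NMEA 0183 GGA sentence parser to decimal-degree fixes.

Every writer can attach a provenance sidecar (command, version, config,
seed) next to its output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .detect import DetectionTable, FishDetection
from .echogen import Echogram, FishTruth
from .errors import InputError, ParameterError
from .reservoir import ClusterSpec, OccupancyGrid

log = logging.getLogger(__name__)

__all__ = [
    "GpsFix",
    "parse_nmea_gga",
    "write_grid", "read_grid",
    "write_echogram", "read_echogram",
    "write_truth_csv", "read_truth_csv",
    "write_detections_csv", "read_detections_csv",
    "write_provenance",
]


# ---------------------------------------------------------------- NMEA GGA

@dataclass(frozen=True)
class GpsFix:
    """One GPS fix in decimal degrees."""

    timestamp: str
    lat: float
    lon: float
    quality: int
    n_sats: int

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ParameterError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ParameterError(f"longitude {self.lon} outside [-180, 180]")
        if self.n_sats < 0:
            raise ParameterError("n_sats must be >= 0")


def _nmea_checksum_ok(line: str) -> bool:
    if not line.startswith("$") or "*" not in line:
        return False
    body, _, check = line[1:].partition("*")
    acc = 0
    for ch in body:
        acc ^= ord(ch)
    try:
        return acc == int(check.strip()[:2], 16)
    except ValueError:
        return False


def _ddmm_to_degrees(value: str, hemisphere: str) -> float:
    v = float(value)
    degrees = int(v // 100)
    minutes = v - 100 * degrees
    out = degrees + minutes / 60.0
    if hemisphere in ("S", "W"):
        out = -out
    return out


def parse_nmea_gga(text: str, strict: bool = False) -> list[GpsFix]:
    """Parse GGA sentences (any talker id) into decimal-degree fixes.

    Non-GGA sentences are ignored.  Sentences with a bad checksum or
    malformed fields are skipped and counted in a logged warning; with
    ``strict=True`` they raise instead.
    """
    fixes: list[GpsFix] = []
    skipped = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line or not line.startswith("$") or "GGA" not in line[:7]:
            continue
        if not _nmea_checksum_ok(line):
            if strict:
                raise InputError(f"NMEA checksum mismatch: {line!r}")
            skipped += 1
            continue
        fields = line[1:line.index("*")].split(",")
        try:
            fixes.append(GpsFix(
                timestamp=fields[1],
                lat=_ddmm_to_degrees(fields[2], fields[3]),
                lon=_ddmm_to_degrees(fields[4], fields[5]),
                quality=int(fields[6]),
                n_sats=int(fields[7]),
            ))
        except (IndexError, ValueError) as exc:
            if strict:
                raise InputError(f"malformed GGA sentence: {line!r}") from exc
            skipped += 1
    if skipped:
        log.warning("skipped %d malformed or checksum-failed GGA sentences", skipped)
    return fixes


# ------------------------------------------------------------- grid PGM I/O

def write_grid(grid: OccupancyGrid, path) -> None:
    """Write a grid as binary PGM (P5; occupied cells white) + JSON sidecar."""
    path = Path(path)
    cells = grid.cells
    if cells.ndim == 3:
        M, N, K = cells.shape
        flat = np.vstack([cells[:, :, k] for k in range(K)])
    else:
        (M, N), K = cells.shape, None
        flat = cells
    Image.fromarray((flat.astype(np.uint8)) * 255, mode="L").save(path, format="PPM")
    sidecar = {
        "M": M, "N": N, "K": K, "cell_size_m": grid.cell_size_m,
        "spec": None if grid.spec is None else {
            "s": grid.spec.s, "area_fraction": grid.spec.area_fraction,
            "seed": grid.spec.seed,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def read_grid(path) -> OccupancyGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    flat = np.asarray(Image.open(path)) > 127
    if meta["K"]:
        M, K = meta["M"], meta["K"]
        cells = np.stack([flat[k * M:(k + 1) * M, :] for k in range(K)], axis=2)
    else:
        cells = flat
    spec = None
    if meta.get("spec"):
        spec = ClusterSpec(**meta["spec"])
    return OccupancyGrid(cells=cells, cell_size_m=meta.get("cell_size_m"), spec=spec)


# ------------------------------------------------------------ echogram I/O

def write_echogram(echo: Echogram, image_path, meta_path) -> None:
    """Write the intensity image (PNG or PGM by suffix) and the JSON sidecar."""
    image_path = Path(image_path)
    img = Image.fromarray(echo.intensity, mode="L")
    if image_path.suffix.lower() == ".pgm":
        img.save(image_path, format="PPM")
    else:
        img.save(image_path, format="PNG")
    meta = {
        "range_m": echo.range_m,
        "surface_row": int(echo.surface_row),
        "bottom_profile": [int(b) for b in echo.bottom_profile],
        "gps_fixes": [[int(p), lat, lon] for p, lat, lon in echo.gps_fixes],
        "ping_times": None if echo.ping_times is None else [float(t) for t in echo.ping_times],
    }
    Path(meta_path).write_text(json.dumps(meta, sort_keys=True))


def read_echogram(image_path, meta_path) -> Echogram:
    intensity = np.asarray(Image.open(image_path).convert("L"))
    meta = json.loads(Path(meta_path).read_text())
    return Echogram(
        intensity=intensity,
        range_m=meta["range_m"],
        surface_row=meta["surface_row"],
        bottom_profile=np.asarray(meta["bottom_profile"], dtype=int),
        gps_fixes=[(int(p), float(a), float(o)) for p, a, o in meta["gps_fixes"]],
        ping_times=None if meta.get("ping_times") is None
        else np.asarray(meta["ping_times"], dtype=float),
    )


# ---------------------------------------------------------------- CSV I/O

def write_truth_csv(truth: list[FishTruth], path) -> None:
    lines = ["ping,row,area_px"]
    for f in truth:
        # repr keeps full float precision so truth round-trips exactly
        lines.append(f"{f.ping_center!r},{f.row_center!r},{f.area_px}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_csv(path) -> list[FishTruth]:
    lines = Path(path).read_text().strip().splitlines()[1:]
    out = []
    for line in lines:
        ping, row, area = line.split(",")
        out.append(FishTruth(ping_center=float(ping), row_center=float(row),
                             area_px=int(area)))
    return out


_DET_HEADER = "id,ping,row,area_px,depth_m,lat,lon,gps_valid"


def write_detections_csv(table: DetectionTable, path) -> None:
    """Header + one row per detection; floats at fixed 6 decimals so a
    write -> read -> write cycle is byte-identical."""
    lines = [_DET_HEADER]
    for d in table:
        lat = "" if d.lat is None else f"{d.lat:.6f}"
        lon = "" if d.lon is None else f"{d.lon:.6f}"
        lines.append(
            f"{d.id},{d.centroid_ping:.6f},{d.centroid_row:.6f},{d.area_px},"
            f"{d.depth_m:.6f},{lat},{lon},{int(d.gps_valid)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_detections_csv(path) -> DetectionTable:
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0] != _DET_HEADER:
        raise InputError(f"unexpected detections CSV header in {path}")
    detections = []
    for line in text[1:]:
        i, ping, row, area, depth, lat, lon, valid = line.split(",")
        detections.append(FishDetection(
            id=int(i), area_px=int(area), centroid_row=float(row),
            centroid_ping=float(ping), depth_m=float(depth),
            lat=float(lat) if lat else None, lon=float(lon) if lon else None,
            gps_valid=bool(int(valid)),
        ))
    return DetectionTable(detections=detections, provenance={"source": str(path)})


def write_provenance(path, command: str, config: dict, seed: int | None) -> None:
    """Attach a ``<path>.provenance.json`` sidecar describing how the file
    next to it was produced."""
    from . import __version__
    payload = {"command": command, "version": __version__,
               "config": config, "seed": seed}
    Path(str(path) + ".provenance.json").write_text(
        json.dumps(payload, sort_keys=True, indent=1))
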