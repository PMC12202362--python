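"""Macular zone partition: fovea plus four parafoveal quadrants.

Zone model (standard 3x3 mm macular analysis grid):

* fovea      — disk of radius 0.5 mm centered on the foveal center;
* parafovea  — annulus from 0.5 mm to 1.5 mm, split into four equal 90°
  sectors: superior, inferior, nasal, temporal;
* outside    — everything beyond 1.5 mm.

Coordinate convention (used consistently with the phantom generator):
image row 0 is the superior edge, the mm origin sits at the field center,
x grows to the image right and y grows upward (toward row 0).  The nasal
quadrant faces the optic disc: image-right for a left eye (OS), image-left
for a right eye (OD).  Quadrant boundaries are the diagonals at 45°, 135°,
225°, 315° from the image-up axis; a pixel whose center lies exactly on a
diagonal is assigned to the clockwise sector.  Radial bands are half-open:
fovea is distance < 0.5 mm, parafovea is 0.5 mm <= distance < 1.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ZONE_FOVEA = 1
ZONE_PARA_S = 2
ZONE_PARA_I = 3
ZONE_PARA_N = 4
ZONE_PARA_T = 5
ZONE_OUTSIDE = 0

ZONE_NAMES = {
    ZONE_OUTSIDE: "outside",
    ZONE_FOVEA: "fovea",
    ZONE_PARA_S: "para_S",
    ZONE_PARA_I: "para_I",
    ZONE_PARA_N: "para_N",
    ZONE_PARA_T: "para_T",
}
ZONE_CODES = {name: code for code, name in ZONE_NAMES.items()}
#: zones carrying metrics, in reporting order
ANALYSIS_ZONES = ("fovea", "para_S", "para_I", "para_N", "para_T")


@dataclass
class ZonePartition:
    """Per-pixel zone id raster plus the geometry that generated it."""

    zones: np.ndarray  # int raster of ZONE_* codes
    center_px: tuple[float, float]  # (row, col), subpixel
    pixel_pitch_mm: float
    r_fovea_mm: float
    r_outer_mm: float
    laterality: str

    def mask(self, zone: str | int) -> np.ndarray:
        code = ZONE_CODES[zone] if isinstance(zone, str) else zone
        return self.zones == code


def pixel_coords_mm(
    shape: tuple[int, int],
    pixel_pitch_mm: float,
    center_px: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (x_mm, y_mm) rasters of pixel-center positions.

    x grows rightward, y grows upward (row 0 = superior edge); origin at
    ``center_px`` (default: geometric image center).
    """
    h, w = shape
    if center_px is None:
        center_px = ((h - 1) / 2.0, (w - 1) / 2.0)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    x_mm = (cols - center_px[1]) * pixel_pitch_mm * np.ones((h, 1))
    y_mm = (center_px[0] - rows) * pixel_pitch_mm * np.ones((1, w))
    return x_mm, y_mm


def build_zones(
    image_shape: tuple[int, int],
    pixel_pitch_mm: float,
    laterality: str,
    center_px: tuple[float, float] | None = None,
    r_fovea_mm: float = 0.5,
    r_outer_mm: float = 1.5,
) -> ZonePartition:
    """Build the fovea/parafoveal-quadrant partition for one image.

    Raises if the outer circle does not fit inside the field.
    """
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be > 0")
    if laterality not in ("OS", "OD"):
        raise ValueError(f"unknown laterality {laterality!r}")
    if not 0 < r_fovea_mm < r_outer_mm:
        raise ValueError("need 0 < r_fovea_mm < r_outer_mm")
    h, w = image_shape
    if center_px is None:
        center_px = ((h - 1) / 2.0, (w - 1) / 2.0)
    # physical field edge lies half a pixel beyond the outermost pixel centers
    half_extent = (
        min(center_px[0], center_px[1], h - 1 - center_px[0], w - 1 - center_px[1]) + 0.5
    ) * pixel_pitch_mm
    if r_outer_mm > half_extent * (1 + 1e-9):
        raise ValueError(
            f"outer radius {r_outer_mm} mm exceeds field half-extent {half_extent:.3f} mm"
        )

    x_mm, y_mm = pixel_coords_mm(image_shape, pixel_pitch_mm, center_px)
    r = np.hypot(x_mm, y_mm)
    # clockwise angle from the image-up axis, in (-pi, pi]
    theta = np.arctan2(x_mm, y_mm)
    # sectors of 90 deg centered on up/right/down/left; boundary pixels fall
    # into the clockwise (next) sector via the half-open binning
    sector = np.floor((theta + np.pi / 4) / (np.pi / 2)).astype(int) % 4
    # sector 0=up, 1=image-right, 2=down, 3=image-left
    if laterality == "OS":
        horiz = {1: ZONE_PARA_N, 3: ZONE_PARA_T}
    else:
        horiz = {1: ZONE_PARA_T, 3: ZONE_PARA_N}
    sector_zone = {0: ZONE_PARA_S, 2: ZONE_PARA_I, **horiz}

    zones = np.full(image_shape, ZONE_OUTSIDE, dtype=np.uint8)
    annulus = (r >= r_fovea_mm) & (r < r_outer_mm)
    for s, code in sector_zone.items():
        zones[annulus & (sector == s)] = code
    zones[r < r_fovea_mm] = ZONE_FOVEA
    return ZonePartition(
        zones, center_px, pixel_pitch_mm, r_fovea_mm, r_outer_mm, laterality
    )


def restrict(mask: np.ndarray, partition: ZonePartition, zone: str | int) -> np.ndarray:
    """Clear mask pixels outside the given zone (idempotent)."""
    mask = np.asarray(mask)
    if mask.shape != partition.zones.shape:
        raise ValueError(
            f"shape mismatch: mask {mask.shape} vs zones {partition.zones.shape}"
        )
    return mask & partition.mask(zone)
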