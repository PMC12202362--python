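"""Reading and writing vessel label maps, masks and cohort manifests.

The en-face artery/vein segmentation convention is a four-class raster:

====  ==========  ==================
code  class       display color
====  ==========  ==================
0     background  black   (0,0,0)
1     artery      red     (255,0,0)
2     vein        blue    (0,0,255)
3     junction    green   (0,255,0)
====  ==========  ==================

Junction pixels mark arteriovenous crossings.  They are *excluded* from
single-class artery/vein masks (to avoid double counting a pixel in both
classes) and *included* in the "all vessels" mask; the choice is exposed via
``binary_mask(..., include_junction_in_class=...)`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image

BACKGROUND, ARTERY, VEIN, JUNCTION = 0, 1, 2, 3
CLASS_CODES = (BACKGROUND, ARTERY, VEIN, JUNCTION)

#: default palette: class code -> RGB triple
PALETTE: dict[int, tuple[int, int, int]] = {
    BACKGROUND: (0, 0, 0),
    ARTERY: (255, 0, 0),
    VEIN: (0, 0, 255),
    JUNCTION: (0, 255, 0),
}

Laterality = Literal["OS", "OD"]
GROUP_COLUMNS = ("eye_id", "group", "laterality", "path", "pixel_pitch_mm")


@dataclass
class VesselLabelMap:
    """Per-pixel artery/vein class raster with physical metadata.

    Attributes
    ----------
    classes : 2-D ``uint8`` array with values in {0, 1, 2, 3}.
    pixel_pitch_mm : physical size of one pixel (isotropic), mm.
    laterality : "OS" (left eye) or "OD" (right eye).
    eye_id : identifier used in manifests and metric tables.
    """

    classes: np.ndarray
    pixel_pitch_mm: float
    laterality: Laterality = "OD"
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if self.laterality not in ("OS", "OD"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        bad = np.setdiff1d(np.unique(self.classes), CLASS_CODES)
        if bad.size:
            raise ValueError(f"unknown class codes present: {bad.tolist()}")
        self.classes = self.classes.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


def binary_mask(
    label_map: VesselLabelMap | np.ndarray,
    class_selector: Literal["artery", "vein", "all"],
    include_junction_in_class: bool = False,
) -> np.ndarray:
    """Boolean vessel mask for one class.

    ``artery``/``vein`` select that class only (junction pixels excluded by
    default); ``all`` selects artery ∪ vein ∪ junction.
    """
    classes = label_map.classes if isinstance(label_map, VesselLabelMap) else np.asarray(label_map)
    if class_selector == "artery":
        mask = classes == ARTERY
        if include_junction_in_class:
            mask |= classes == JUNCTION
    elif class_selector == "vein":
        mask = classes == VEIN
        if include_junction_in_class:
            mask |= classes == JUNCTION
    elif class_selector == "all":
        mask = classes != BACKGROUND
    else:
        raise ValueError(f"unknown class selector {class_selector!r}")
    return mask


def write_label_map(label_map: VesselLabelMap, path: str | Path) -> Path:
    """Write the class raster as an indexed PNG using the standard palette."""
    path = Path(path)
    img = Image.fromarray(label_map.classes, mode="P")
    flat_palette = np.zeros(768, dtype=np.uint8)
    for code, rgb in PALETTE.items():
        flat_palette[3 * code : 3 * code + 3] = rgb
    img.putpalette(flat_palette.tolist())
    img.save(path)
    return path


def read_label_map(
    path: str | Path,
    pixel_pitch_mm: float,
    laterality: Laterality = "OD",
    eye_id: str = "",
    palette: dict[int, tuple[int, int, int]] | None = None,
    color_tolerance: int = 0,
) -> VesselLabelMap:
    """Read a label map from an indexed/RGB PNG or TIFF.

    Colors must match the palette exactly, or within ``color_tolerance``
    (maximum per-channel distance) when nearest-palette matching is wanted for
    anti-aliased exports.  A single-channel image with values {0, 255} is
    accepted as a binary all-vessel mask: vessel pixels are stored with class
    code 1 and such maps carry no artery/vein distinction, so only
    ``binary_mask(map, "all")`` is meaningful on them.
    """
    palette = PALETTE if palette is None else palette
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    if img.mode == "P":
        raster = np.asarray(img, dtype=np.uint8)
        bad = np.setdiff1d(np.unique(raster), list(palette))
        if bad.size:
            raise ValueError(f"{path}: unknown palette indices {bad.tolist()}")
        return VesselLabelMap(raster, pixel_pitch_mm, laterality, eye_id)
    if img.mode in ("L", "1", "I;16"):
        arr = np.asarray(img.convert("L"))
        values = np.unique(arr)
        if not np.all(np.isin(values, [0, 255])):
            raise ValueError(
                f"{path}: grayscale input must be binary 0/255, got values {values.tolist()}"
            )
        return VesselLabelMap((arr > 0).astype(np.uint8), pixel_pitch_mm, laterality, eye_id)

    rgb = np.asarray(img.convert("RGB"), dtype=np.int16)
    h, w, _ = rgb.shape
    raster = np.full((h, w), -1, dtype=np.int16)
    # per-palette-entry max channel distance
    best_dist = np.full((h, w), np.iinfo(np.int16).max, dtype=np.int16)
    for code, color in palette.items():
        dist = np.abs(rgb - np.asarray(color, dtype=np.int16)).max(axis=2)
        closer = dist < best_dist
        raster[closer] = code
        best_dist = np.minimum(best_dist, dist.astype(np.int16))
    unmapped = best_dist > color_tolerance
    if np.any(unmapped):
        ys, xs = np.nonzero(unmapped)
        offending = np.unique(rgb[ys, xs], axis=0)[:5]
        raise ValueError(
            f"{path}: {unmapped.sum()} pixels with colors outside the palette "
            f"(tolerance {color_tolerance}); examples: "
            + ", ".join(str(tuple(int(v) for v in c)) for c in offending)
        )
    return VesselLabelMap(raster.astype(np.uint8), pixel_pitch_mm, laterality, eye_id)


def load_cohort_manifest(
    path: str | Path,
    known_groups: list[str] | None = None,
) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    Required columns: eye_id, group, laterality, path, pixel_pitch_mm.
    Optional covariates (subject_id, age, duration_years, sex) pass through.
    """
    table = pd.read_csv(path)
    missing = [c for c in GROUP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing required columns {missing}")
    dupes = table["eye_id"][table["eye_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"manifest {path}: duplicate eye_id values {dupes}")
    bad_lat = table.loc[~table["laterality"].isin(["OS", "OD"])]
    if len(bad_lat):
        row = bad_lat.iloc[0]
        raise ValueError(
            f"manifest {path}: eye {row['eye_id']}: unknown laterality {row['laterality']!r}"
        )
    if (table["pixel_pitch_mm"] <= 0).any():
        raise ValueError(f"manifest {path}: pixel_pitch_mm must be > 0")
    if known_groups is not None:
        bad = table.loc[~table["group"].isin(known_groups)]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"manifest {path}: eye {row['eye_id']}: unknown group {row['group']!r}"
            )
    return table
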