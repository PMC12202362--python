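"""Zone-wise vascular metrics for en-face artery/vein label maps.

Raster metrics (per zone, per vessel class):

* ``VD``  — vessel density, vessel pixels / zone pixels;
* ``VDI`` — vessel diameter index, vessel pixels / skeleton pixels (mean
  caliber, in px and µm);
* ``VLF`` — vessel length fraction, skeleton pixels / zone pixels;
* ``FD``  — box-counting fractal dimension of the skeleton.

Track metrics (per centerline track, averaged per zone x class):

* ``MDAC``   — mean direction angle change between unit chord vectors taken
  ``step`` points apart (radians);
* ``LC`` / ``LX`` — arc (polyline) length and chord (endpoint) length;
* ``TSC`` — total squared curvature, the discrete integral of C(t)^2 over arc
  length, with ``TSC_LX`` and ``TSC_LC`` its chord- and arc-length-normalized
  variants.

Curvature is estimated by Gaussian-smoothing the coordinate sequences
(default sigma 2 samples) and central differences; raw pixel chains alias
curvature badly.  Undefined quantities (empty zones, no skeleton, closed
chords) propagate as NaN, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .image_io import VesselLabelMap, binary_mask
from .skeleton import VesselTrack, tracks_from_mask
from .zones import ANALYSIS_ZONES, ZonePartition

VESSEL_CLASSES = ("artery", "vein", "all")


@dataclass
class MetricConfig:
    """Tunable parameters of the metric computations."""

    mdac_step: int = 5
    curvature_sigma: float = 2.0
    min_track_length: int | None = None  # default: 2*mdac_step + 1
    fd_min_box: int = 2
    track_weighting: str = "unweighted"  # or "length"
    skeleton_method: str = "zhang"

    @property
    def min_len(self) -> int:
        return self.min_track_length if self.min_track_length is not None else 2 * self.mdac_step + 1


# ---------------------------------------------------------------------------
# raster metrics


def vessel_density(mask: np.ndarray, zone_mask: np.ndarray) -> float:
    """Fraction of zone pixels occupied by vessels; NaN for an empty zone."""
    mask = np.asarray(mask, bool)
    zone_mask = np.asarray(zone_mask, bool)
    if mask.shape != zone_mask.shape:
        raise ValueError("mask and zone raster shapes differ")
    n = int(zone_mask.sum())
    if n == 0:
        return float("nan")
    return float(mask[zone_mask].sum() / n)


def vessel_diameter_index(
    mask: np.ndarray, skeleton: np.ndarray, zone_mask: np.ndarray
) -> float:
    """Mean vessel caliber in px: zone vessel pixels per zone skeleton pixel.

    NaN when the zone holds no skeleton pixels.
    """
    mask = np.asarray(mask, bool)
    skeleton = np.asarray(skeleton, bool)
    zone_mask = np.asarray(zone_mask, bool)
    s = int((skeleton & zone_mask).sum())
    if s == 0:
        return float("nan")
    return float((mask & zone_mask).sum() / s)


def vessel_length_fraction(skeleton: np.ndarray, zone_mask: np.ndarray) -> float:
    """Skeleton pixels per zone pixel (normalized total vessel length)."""
    skeleton = np.asarray(skeleton, bool)
    zone_mask = np.asarray(zone_mask, bool)
    n = int(zone_mask.sum())
    if n == 0:
        return float("nan")
    return float((skeleton & zone_mask).sum() / n)


def fractal_dimension(
    skeleton: np.ndarray,
    zone_mask: np.ndarray | None = None,
    min_box: int = 2,
) -> float:
    """Box-counting fractal dimension of (zone-clipped) skeleton pixels.

    Boxes of side 2, 4, 8, ... up to min(image)/4, grid anchored at the
    occupied bounding-box origin; FD is minus the OLS slope of
    log N(eps) vs log eps over scales with N(eps) >= 2.  NaN when fewer than
    two usable scales remain.
    """
    skel = np.asarray(skeleton, bool)
    if zone_mask is not None:
        skel = skel & np.asarray(zone_mask, bool)
    ys, xs = np.nonzero(skel)
    if len(ys) == 0:
        return float("nan")
    ys = ys - ys.min()
    xs = xs - xs.min()
    max_box = min(skeleton.shape) // 4
    sizes, counts = [], []
    eps = min_box
    while eps <= max_box:
        n = len(set(zip(ys // eps, xs // eps)))
        if n >= 2:
            sizes.append(eps)
            counts.append(n)
        eps *= 2
    if len(sizes) < 2:
        return float("nan")
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# track metrics


def curve_length(track: np.ndarray | VesselTrack) -> float:
    """Arc length LC: sum of consecutive point distances (px)."""
    pts = _points(track)
    if len(pts) < 2:
        raise ValueError("curve length needs >= 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def chord_length(track: np.ndarray | VesselTrack) -> float:
    """Chord length LX: distance between the first and last point (px)."""
    pts = _points(track)
    if len(pts) < 2:
        raise ValueError("chord length needs >= 2 points")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def _points(track) -> np.ndarray:
    pts = track.points if isinstance(track, VesselTrack) else np.asarray(track)
    return np.asarray(pts, dtype=float)


def curvature_profile(
    track: np.ndarray | VesselTrack, sigma: float = 2.0
) -> np.ndarray:
    """Per-point signed curvature C(t) = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2).

    Derivatives are central differences of the Gaussian-smoothed coordinate
    sequences (``sigma`` in samples); endpoints use one-sided differences.
    """
    pts = _points(track)
    if len(pts) < 5:
        raise ValueError("curvature profile needs >= 5 points")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError("degenerate track: coincident consecutive points")
    if sigma > 0:
        # pad by quadratic extrapolation so the smoother does not flatten the
        # curve (and bias curvature low) near the endpoints
        pad = int(np.ceil(3 * sigma))
        m = min(len(pts), max(5, int(4 * sigma) + 1))
        idx = np.arange(len(pts), dtype=float)
        ext = [pts]
        for side in (0, -1):
            sl = slice(0, m) if side == 0 else slice(-m, None)
            t_new = idx[:pad][::-1] * -1 - 1 if side == 0 else idx[-1] + 1 + np.arange(pad)
            cols = [np.polyval(np.polyfit(idx[sl], pts[sl, d], 2), t_new) for d in (0, 1)]
            block = np.stack(cols, axis=1)
            ext = [block] + ext if side == 0 else ext + [block]
        padded = np.concatenate(ext)
        x = gaussian_filter1d(padded[:, 0], sigma, mode="nearest")[pad:-pad]
        y = gaussian_filter1d(padded[:, 1], sigma, mode="nearest")[pad:-pad]
    else:
        x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.gradient(x), np.gradient(y)
    x2, y2 = np.gradient(x1), np.gradient(y1)
    denom = (x1**2 + y1**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, (x1 * y2 - y1 * x2) / denom, 0.0)
    return c


def total_squared_curvature(
    track: np.ndarray | VesselTrack, sigma: float = 2.0
) -> float:
    """TSC: the discrete integral of C(t)^2 over arc length."""
    pts = _points(track)
    c = curvature_profile(pts, sigma)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return float(np.trapezoid(c**2, s))


def tsc_lx(track: np.ndarray | VesselTrack, sigma: float = 2.0) -> float:
    """TSC normalized by chord length; NaN for a closed track (LX = 0)."""
    lx = chord_length(track)
    if lx == 0:
        return float("nan")
    return total_squared_curvature(track, sigma) / lx


def tsc_lc(track: np.ndarray | VesselTrack, sigma: float = 2.0) -> float:
    """TSC normalized by arc length."""
    return total_squared_curvature(track, sigma) / curve_length(track)


def mdac(track: np.ndarray | VesselTrack, step: int = 5) -> float:
    """Mean direction angle change (radians) at a fixed index step.

    For each interior index n, the angle between the unit vectors of the
    chords (P[n-step] -> P[n]) and (P[n] -> P[n+step]), averaged; the cosine
    is clamped to [-1, 1] before arccos.  NaN when the track is shorter than
    2*step + 1 points.
    """
    pts = _points(track)
    n = len(pts)
    if n < 2 * step + 1:
        return float("nan")
    a = pts[step:-step] - pts[: -2 * step]
    b = pts[2 * step :] - pts[step:-step]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    if not np.any(ok):
        return float("nan")
    cosang = np.clip(np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok]), -1.0, 1.0)
    ang = np.arccos(cosang)
    ang[cosang > 1 - 1e-12] = 0.0  # below float resolution of the directions
    return float(np.mean(ang))


# ---------------------------------------------------------------------------
# aggregation


_TRACK_METRICS = ("MDAC", "LC", "LX", "TSC", "TSC_LX", "TSC_LC")


def _track_aggregates(
    tracks: list[VesselTrack], config: MetricConfig
) -> dict[str, float]:
    rows = []
    weights = []
    for tr in tracks:
        pts = _points(tr)
        lc = curve_length(pts)
        lx = chord_length(pts)
        if len(pts) >= 5:
            tsc = total_squared_curvature(pts, config.curvature_sigma)
        else:
            tsc = float("nan")
        rows.append(
            {
                "MDAC": mdac(pts, config.mdac_step),
                "LC": lc,
                "LX": lx,
                "TSC": tsc,
                "TSC_LX": tsc / lx if (lx > 0 and np.isfinite(tsc)) else float("nan"),
                "TSC_LC": tsc / lc if np.isfinite(tsc) else float("nan"),
            }
        )
        weights.append(lc)
    out: dict[str, float] = {"n_tracks": float(len(tracks))}
    if not rows:
        out.update({m: float("nan") for m in _TRACK_METRICS})
        return out
    df = pd.DataFrame(rows)
    w = np.asarray(weights)
    for m in _TRACK_METRICS:
        vals = df[m].to_numpy()
        good = np.isfinite(vals)
        if not good.any():
            out[m] = float("nan")
        elif config.track_weighting == "length":
            out[m] = float(np.average(vals[good], weights=w[good]))
        else:
            out[m] = float(np.mean(vals[good]))
    return out


def metrics_by_zone(
    label_map: VesselLabelMap,
    partition: ZonePartition,
    config: MetricConfig | None = None,
    tracks_by_class: dict[str, list[VesselTrack]] | None = None,
) -> pd.DataFrame:
    """All metrics, one row per zone x vessel class (plus whole-image rows).

    Per class ("artery", "vein", "all"), the class mask is skeletonized once
    and decomposed into tracks; raster metrics are computed per zone and the
    track metrics are averaged over tracks attributed to the zone by majority
    pixel membership.  Rows with ``zone == "image"`` carry the image-wide
    metrics (the whole-field FD in particular).
    """
    config = config or MetricConfig()
    records = []
    full = np.ones(label_map.shape, dtype=bool)
    for cls in VESSEL_CLASSES:
        mask = binary_mask(label_map, cls)
        skel, tracks = tracks_from_mask(
            mask, config.min_len, label_map, partition, method=config.skeleton_method
        )
        if tracks_by_class is not None and cls in tracks_by_class:
            tracks = tracks_by_class[cls]
        for zone in ANALYSIS_ZONES + ("image",):
            zmask = full if zone == "image" else partition.mask(zone)
            ztracks = tracks if zone == "image" else [t for t in tracks if t.zone == zone]
            vdi_px = vessel_diameter_index(mask, skel, zmask)
            rec = {
                "eye_id": label_map.eye_id,
                "zone": zone,
                "vessel_class": cls,
                "VD": vessel_density(mask, zmask),
                "VDI_px": vdi_px,
                "VDI_um": vdi_px * label_map.pixel_pitch_mm * 1000.0,
                "VLF": vessel_length_fraction(skel, zmask),
                "FD": fractal_dimension(skel, None if zone == "image" else zmask, config.fd_min_box),
                **_track_aggregates(ztracks, config),
            }
            records.append(rec)
    df = pd.DataFrame(records)
    return df
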