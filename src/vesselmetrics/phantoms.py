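"""Synthetic vessel phantoms with analytically known geometry.

The study images this pipeline targets (3x3 mm en-face OCTA artery/vein
segmentations) are not publicly deposited, so every test and calibration runs
on phantoms: parametric centerlines (lines, circular arcs, sinusoids, cubic
Beziers) with exactly known arc length, chord length and curvature, rasterized
into the four-class label-map convention of :mod:`vesselmetrics.image_io` at a
configurable pixel pitch.  Cohorts of phantom eyes with per-zone density and
tortuosity effect sizes stand in for patient groups.

Coordinates are in mm with the origin at the field center, x to the image
right and y upward (see :mod:`vesselmetrics.zones`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .image_io import ARTERY, BACKGROUND, JUNCTION, VEIN, VesselLabelMap, write_label_map
from .zones import ANALYSIS_ZONES, ZonePartition, build_zones

CurveKind = Literal["line", "circular_arc", "sinusoid", "cubic_bezier"]

__all__ = [
    "CenterlineSpec",
    "PhantomTruth",
    "CohortSpec",
    "Cohort",
    "sample_centerline",
    "analytic_truth",
    "rasterize",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CenterlineSpec:
    """One parametric vessel centerline.

    ``params`` by kind (all lengths mm):

    * ``line``: ``p0``, ``p1`` endpoints.
    * ``circular_arc``: ``center``, ``radius``, ``angle_start``,
      ``angle_span`` (radians; positive = counterclockwise in mm coords).
    * ``sinusoid``: ``p0``, ``p1`` baseline endpoints, ``amplitude``,
      ``frequency`` (cycles per mm of baseline), optional ``phase``.
    * ``cubic_bezier``: ``control_points`` (4 x 2).
    """

    kind: CurveKind
    params: dict
    width_mm: float
    vessel_class: Literal["artery", "vein"] = "artery"
    n_samples: int = 100

    def __post_init__(self) -> None:
        if self.width_mm <= 0:
            raise ValueError("width_mm must be > 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.vessel_class not in ("artery", "vein"):
            raise ValueError(f"unknown vessel class {self.vessel_class!r}")


@dataclass
class PhantomTruth:
    """Closed-form/quadrature ground truth for one centerline."""

    arc_length_mm: float
    chord_length_mm: float
    curvature: np.ndarray  # C(t) at the n_samples arc-length-uniform points, 1/mm
    tsc: float  # integral of C^2 over arc length, 1/mm
    tsc_lx: float | None  # tsc / chord length; None when chord degenerate
    tsc_lc: float  # tsc / arc length, 1/mm^2
    mdac: float  # mean direction angle change at the requested step, radians
    mdac_step: int
    vessel_class: str = "artery"
    width_mm: float = float("nan")
    n_pixels: int | None = None  # filled by rasterize


# ---------------------------------------------------------------------------
# parametric forms


def _parametric(spec: CenterlineSpec):
    """Return (position, velocity, acceleration) callables of t in [0, 1]."""
    p = spec.params
    if spec.kind == "line":
        p0 = np.asarray(p["p0"], float)
        p1 = np.asarray(p["p1"], float)
        d = p1 - p0
        return (
            lambda t: p0 + np.multiply.outer(t, d),
            lambda t: np.broadcast_to(d, np.shape(t) + (2,)).copy(),
            lambda t: np.zeros(np.shape(t) + (2,)),
        )
    if spec.kind == "circular_arc":
        c = np.asarray(p["center"], float)
        r = float(p["radius"])
        a0 = float(p["angle_start"])
        span = float(p["angle_span"])
        if r <= 0 or span == 0:
            raise ValueError("arc needs radius > 0 and nonzero span")

        def pos(t):
            a = a0 + span * np.asarray(t, float)
            return c + r * np.stack([np.cos(a), np.sin(a)], axis=-1)

        def vel(t):
            a = a0 + span * np.asarray(t, float)
            return r * span * np.stack([-np.sin(a), np.cos(a)], axis=-1)

        def acc(t):
            a = a0 + span * np.asarray(t, float)
            return -r * span**2 * np.stack([np.cos(a), np.sin(a)], axis=-1)

        return pos, vel, acc
    if spec.kind == "sinusoid":
        p0 = np.asarray(p["p0"], float)
        p1 = np.asarray(p["p1"], float)
        amp = float(p["amplitude"])
        freq = float(p["frequency"])
        phase = float(p.get("phase", 0.0))
        d = p1 - p0
        length = float(np.hypot(*d))
        if length == 0:
            raise ValueError("sinusoid baseline is degenerate")
        tangent = d / length
        normal = np.array([-tangent[1], tangent[0]])
        omega = 2 * np.pi * freq * length  # radians per unit t

        def pos(t):
            t = np.asarray(t, float)
            along = np.multiply.outer(t, d)
            off = amp * np.sin(omega * t + phase)
            return p0 + along + np.multiply.outer(off, normal)

        def vel(t):
            t = np.asarray(t, float)
            doff = amp * omega * np.cos(omega * t + phase)
            return np.broadcast_to(d, np.shape(t) + (2,)) + np.multiply.outer(doff, normal)

        def acc(t):
            t = np.asarray(t, float)
            ddoff = -amp * omega**2 * np.sin(omega * t + phase)
            return np.multiply.outer(ddoff, normal)

        return pos, vel, acc
    if spec.kind == "cubic_bezier":
        cp = np.asarray(p["control_points"], float)
        if cp.shape != (4, 2):
            raise ValueError("cubic_bezier needs 4 control points")
        b0, b1, b2, b3 = cp

        def pos(t):
            t = np.asarray(t, float)[..., None]
            u = 1 - t
            return u**3 * b0 + 3 * u**2 * t * b1 + 3 * u * t**2 * b2 + t**3 * b3

        def vel(t):
            t = np.asarray(t, float)[..., None]
            u = 1 - t
            return 3 * u**2 * (b1 - b0) + 6 * u * t * (b2 - b1) + 3 * t**2 * (b3 - b2)

        def acc(t):
            t = np.asarray(t, float)[..., None]
            u = 1 - t
            return 6 * u * (b2 - 2 * b1 + b0) + 6 * t * (b3 - 2 * b2 + b1)

        return pos, vel, acc
    raise ValueError(f"unknown curve kind {spec.kind!r}")


def _speed(spec: CenterlineSpec):
    _, vel, _ = _parametric(spec)
    return lambda t: np.linalg.norm(np.atleast_2d(vel(t)), axis=-1)


def _arc_length_params(spec: CenterlineSpec, n: int, dense: int = 4096) -> np.ndarray:
    """Parameter values giving n points uniform in arc length."""
    speed = _speed(spec)
    tg = np.linspace(0.0, 1.0, dense + 1)
    sp = speed(tg)
    cum = np.concatenate([[0.0], np.cumsum((sp[1:] + sp[:-1]) / 2 * np.diff(tg))])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate curve with zero length")
    targets = np.linspace(0.0, total, n)
    return np.interp(targets, cum, tg)


def sample_centerline(spec: CenterlineSpec) -> np.ndarray:
    """Sample ``n_samples`` points at uniform arc-length spacing (mm).

    Lines and circular arcs are reparametrized exactly; sinusoids and Beziers
    via a dense cumulative-arc-length table.
    """
    pos, _, _ = _parametric(spec)
    if spec.kind in ("line", "circular_arc"):
        t = np.linspace(0.0, 1.0, spec.n_samples)
    else:
        t = _arc_length_params(spec, spec.n_samples)
    pts = np.atleast_2d(pos(t))
    if np.hypot(*(pts[-1] - pts[0])) == 0 and spec.kind == "line":
        raise ValueError("degenerate line with zero length")
    return pts


def analytic_truth(spec: CenterlineSpec, mdac_step: int = 5) -> PhantomTruth:
    """Ground-truth metrics from the parametric form (never from a raster).

    Arc length and total squared curvature are adaptive quadratures of the
    exact derivatives; MDAC applies its defining chord-angle formula to the
    exact arc-length-uniform sample points.
    """
    pos, vel, acc = _parametric(spec)

    def speed1(t):
        return float(np.linalg.norm(vel(t)))

    def curv(t):
        v = np.atleast_2d(vel(t))
        a = np.atleast_2d(acc(t))
        num = v[..., 0] * a[..., 1] - v[..., 1] * a[..., 0]
        den = (v[..., 0] ** 2 + v[..., 1] ** 2) ** 1.5
        return num / den

    lc = quad(speed1, 0, 1, limit=200)[0]
    if lc <= 0:
        raise ValueError("degenerate curve with zero length")
    tsc = quad(lambda t: float(np.asarray(curv(t)).reshape(-1)[0] ** 2) * speed1(t), 0, 1, limit=200)[0]

    pts = sample_centerline(spec)
    lx = float(np.hypot(*(pts[-1] - pts[0])))

    if spec.kind in ("line", "circular_arc"):
        tcurv = np.linspace(0.0, 1.0, spec.n_samples)
    else:
        tcurv = _arc_length_params(spec, spec.n_samples)
    curvature = np.asarray(curv(tcurv), float).reshape(-1)

    mdac = _mdac_from_points(pts, mdac_step)
    closed = lx < 1e-12
    return PhantomTruth(
        arc_length_mm=lc,
        chord_length_mm=lx,
        curvature=curvature,
        tsc=tsc,
        tsc_lx=None if closed else tsc / lx,
        tsc_lc=tsc / lc,
        mdac=mdac,
        mdac_step=mdac_step,
        vessel_class=spec.vessel_class,
        width_mm=spec.width_mm,
    )


def _mdac_from_points(points: np.ndarray, step: int) -> float:
    """Mean direction angle change of an ordered point sequence.

    Average over n of the angle between the unit chord vectors
    (P[n-step] -> P[n]) and (P[n] -> P[n+step]); NaN when the sequence is
    shorter than 2*step + 1 points.
    """
    n = len(points)
    if n < 2 * step + 1:
        return float("nan")
    a = points[step:-step] - points[: -2 * step]
    b = points[2 * step :] - points[step:-step]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    cosang = np.clip(np.einsum("ij,ij->i", a, b)[ok] / (na[ok] * nb[ok]), -1.0, 1.0)
    ang = np.arccos(cosang)
    ang[cosang > 1 - 1e-12] = 0.0  # below float resolution of the directions
    return float(np.mean(ang))


# ---------------------------------------------------------------------------
# rasterization


def _mm_to_px(points_mm: np.ndarray, shape: tuple[int, int], pitch: float) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    cols = points_mm[:, 0] / pitch + cx
    rows = cy - points_mm[:, 1] / pitch
    return np.stack([rows, cols], axis=1)


def _paint_ribbon(
    mask: np.ndarray,
    polyline_px: np.ndarray,
    half_width_px: float,
) -> None:
    """Paint pixels within half_width of the polyline (flat end caps).

    A pixel is painted when its perpendicular distance to some segment (with
    projection inside the segment) is <= half_width, or when it lies within
    half_width of an interior vertex (round joints keep bends gap-free).
    """
    h, w = mask.shape
    rmin = max(int(np.floor(polyline_px[:, 0].min() - half_width_px - 1)), 0)
    rmax = min(int(np.ceil(polyline_px[:, 0].max() + half_width_px + 1)), h - 1)
    cmin = max(int(np.floor(polyline_px[:, 1].min() - half_width_px - 1)), 0)
    cmax = min(int(np.ceil(polyline_px[:, 1].max() + half_width_px + 1)), w - 1)
    if rmax < rmin or cmax < cmin:
        return
    rows = np.arange(rmin, rmax + 1)
    cols = np.arange(cmin, cmax + 1)
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2).astype(float)

    # cheap superset filter: exact segment tests only near the polyline
    tree = cKDTree(polyline_px)
    d_pt, _ = tree.query(grid, distance_upper_bound=half_width_px + 1.0)
    grid = grid[np.isfinite(d_pt)]
    if not len(grid):
        return
    painted = np.zeros(len(grid), dtype=bool)

    seg_a = polyline_px[:-1]
    seg_d = polyline_px[1:] - seg_a
    seg_len2 = np.einsum("ij,ij->i", seg_d, seg_d)
    keep = seg_len2 > 0
    seg_a, seg_d, seg_len2 = seg_a[keep], seg_d[keep], seg_len2[keep]

    chunk = max(1, int(4e6 // max(len(grid), 1)))
    for start in range(0, len(seg_a), chunk):
        a = seg_a[start : start + chunk]
        d = seg_d[start : start + chunk]
        l2 = seg_len2[start : start + chunk]
        rel = grid[:, None, :] - a[None, :, :]  # (M, S, 2)
        t = np.einsum("msj,sj->ms", rel, d) / l2
        perp = rel - t[..., None] * d[None, :, :]
        dist2 = np.einsum("msj,msj->ms", perp, perp)
        hit = (t >= 0.0) & (t <= 1.0) & (dist2 <= half_width_px**2)
        painted |= hit.any(axis=1)

    # round joints only where the polyline actually turns; straight joints
    # are already covered by the adjoining segments
    if len(seg_a) > 1:
        unit = seg_d / np.sqrt(seg_len2)[:, None]
        cos_turn = np.einsum("ij,ij->i", unit[:-1], unit[1:])
        sharp = seg_a[1:][cos_turn < np.cos(1e-3)]  # joints turning > 1 mrad
        for start in range(0, len(sharp), 256):
            v = sharp[start : start + 256]
            d2 = ((grid[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
            painted |= (d2 <= half_width_px**2).any(axis=1)

    idx = grid[painted].astype(int)
    mask[idx[:, 0], idx[:, 1]] = True


def _dense_polyline_px(
    spec: CenterlineSpec, shape: tuple[int, int], pitch: float
) -> np.ndarray:
    """Centerline sampled at >= 2 points per pixel of arc length, px coords."""
    truth_lc = None
    if spec.kind == "line":
        p = spec.params
        truth_lc = float(np.hypot(*(np.asarray(p["p1"], float) - np.asarray(p["p0"], float))))
    elif spec.kind == "circular_arc":
        truth_lc = abs(spec.params["angle_span"]) * spec.params["radius"]
    if truth_lc is None:
        pts = sample_centerline(replace(spec, n_samples=max(spec.n_samples, 64)))
        truth_lc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    n_dense = max(spec.n_samples, int(np.ceil(2 * truth_lc / pitch)) + 1, 2)
    pts_mm = sample_centerline(replace(spec, n_samples=n_dense))
    return _mm_to_px(pts_mm, shape, pitch)


def rasterize(
    specs: list[CenterlineSpec],
    image_shape: tuple[int, int] = (304, 304),
    pixel_pitch_mm: float = 3.0 / 304,
    seed: int | None = None,
    dropout: float = 0.0,
    laterality: str = "OD",
    eye_id: str = "phantom",
    mdac_step: int = 5,
) -> tuple[VesselLabelMap, list[PhantomTruth]]:
    """Rasterize centerlines into an artery/vein label map.

    Each centerline becomes a ribbon of its requested width; pixels covered by
    both an artery and a vein ribbon are marked as junctions.  ``dropout``
    removes vessel pixels independently with that probability (seeded), a
    crude stand-in for segmentation noise.
    """
    half_checks = [s.width_mm / pixel_pitch_mm for s in specs]
    too_thin = [w for w in half_checks if w < 1.0]
    if too_thin:
        raise ValueError(
            f"vessel width {min(too_thin) * pixel_pitch_mm:.4f} mm is below one pixel "
            f"({pixel_pitch_mm:.4f} mm); increase width or refine pixel pitch"
        )
    artery_mask = np.zeros(image_shape, dtype=bool)
    vein_mask = np.zeros(image_shape, dtype=bool)
    truths: list[PhantomTruth] = []
    for spec in specs:
        target = artery_mask if spec.vessel_class == "artery" else vein_mask
        own = np.zeros(image_shape, dtype=bool)
        poly = _dense_polyline_px(spec, image_shape, pixel_pitch_mm)
        _paint_ribbon(own, poly, spec.width_mm / pixel_pitch_mm / 2.0)
        target |= own
        truth = analytic_truth(spec, mdac_step=mdac_step)
        truth.n_pixels = int(own.sum())
        truths.append(truth)

    classes = np.zeros(image_shape, dtype=np.uint8)
    classes[artery_mask] = ARTERY
    classes[vein_mask] = VEIN
    classes[artery_mask & vein_mask] = JUNCTION
    if dropout > 0:
        rng = np.random.default_rng(seed)
        drop = rng.random(image_shape) < dropout
        classes[drop] = BACKGROUND
    return (
        VesselLabelMap(classes, pixel_pitch_mm, laterality, eye_id),
        truths,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Design of a synthetic multi-group cohort of phantom eyes.

    Defaults emulate a three-group study (healthy controls, diabetics without
    retinopathy, diabetics with early retinopathy) on 3x3 mm scans at
    304x304 px: large/medium vessels only, combined artery+vein density around
    0.18 in the parafoveal quadrants and sparse central vasculature around the
    avascular zone.  Effect sizes are injected as additive per-zone per-class
    density offsets or per-group sinusoid-amplitude (tortuosity) offsets.
    """

    group_names: tuple[str, ...] = ("control", "NDR", "NPDR")
    eyes_per_group: int = 10
    image_shape: tuple[int, int] = (304, 304)
    pixel_pitch_mm: float = 3.0 / 304
    #: per-zone combined (artery+vein) target vessel density
    zone_density: dict[str, float] = field(
        default_factory=lambda: {
            "fovea": 0.06,
            "para_S": 0.18,
            "para_I": 0.18,
            "para_N": 0.18,
            "para_T": 0.18,
        }
    )
    #: group -> {(zone, vessel_class): additive VD offset}
    density_offsets: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    #: relative between-eye SD of per-zone per-class density targets
    eye_density_rel_sd: float = 0.08
    #: baseline sinusoid amplitude (mm) controlling tortuosity
    sinusoid_amplitude_mm: float = 0.02
    #: group -> additive amplitude offset (mm)
    amplitude_offsets: dict[str, float] = field(default_factory=dict)
    vessel_width_mm: tuple[float, float] = (0.035, 0.065)
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eyes_per_group < 2:
            raise ValueError("eyes_per_group must be >= 2")
        for z, d in self.zone_density.items():
            if not 0 <= d < 1:
                raise ValueError(f"zone {z}: density target {d} outside [0, 1)")
        for g, offs in self.density_offsets.items():
            if g not in self.group_names:
                raise ValueError(f"density offset for unknown group {g!r}")
            for (z, cls), off in offs.items():
                if self.zone_density.get(z, 0) / 2 + off >= 1:
                    raise ValueError(f"infeasible density target in zone {z!r}")


@dataclass
class Cohort:
    """In-memory phantom cohort: manifest + label maps + realized truth."""

    manifest: pd.DataFrame
    label_maps: dict[str, VesselLabelMap]
    truth: pd.DataFrame  # eye_id, zone, vessel_class, target_vd, realized_vd


def _sample_point_in_zone(rng, zone_mask, shape, pitch):
    rows, cols = np.nonzero(zone_mask)
    i = rng.integers(len(rows))
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    x = (cols[i] + rng.uniform(-0.5, 0.5) - cx) * pitch
    y = (cy - rows[i] - rng.uniform(-0.5, 0.5)) * pitch
    return np.array([x, y])


def _fill_zone_class(
    rng: np.random.Generator,
    class_mask: np.ndarray,
    other_mask: np.ndarray,
    zone_mask: np.ndarray,
    target_vd: float,
    spec: CohortSpec,
    amplitude: float,
    vessel_class: str,
    avoid_mask: np.ndarray | None = None,
    max_curves: int = 200,
) -> None:
    """Add short sinusoidal vessels inside a zone until its class VD target.

    Density is measured junction-exclusively (pixels also covered by the other
    vessel class do not count), matching the metric convention; the final
    curves shrink toward the remaining deficit so the realized density lands
    within a few percent of the target.  Candidate curves touching
    ``avoid_mask`` are rejected (used to keep parafoveal vessels out of the
    fovea, whose small area makes spill-in distort its density badly).
    """
    zone_px = int(zone_mask.sum())
    if zone_px == 0 or target_vd <= 0:
        return
    shape = class_mask.shape
    pitch = spec.pixel_pitch_mm
    half_field = min(shape) * pitch / 2 * 0.98
    for _ in range(max_curves):
        frac = (class_mask & ~other_mask)[zone_mask].mean()
        deficit_px = (target_vd - frac) * zone_px
        if deficit_px <= 0:
            break
        width = rng.uniform(*spec.vessel_width_mm)
        # curve length that would paint roughly the deficit, clamped
        want_len = deficit_px * pitch**2 / width
        length = float(np.clip(want_len, 0.12, 0.55))
        center = _sample_point_in_zone(rng, zone_mask, shape, pitch)
        ang = rng.uniform(0, 2 * np.pi)
        d = np.array([np.cos(ang), np.sin(ang)]) * length / 2
        p0, p1 = center - d, center + d
        p0 = np.clip(p0, -half_field, half_field)
        p1 = np.clip(p1, -half_field, half_field)
        if np.hypot(*(p1 - p0)) < 0.05:
            continue
        cspec = CenterlineSpec(
            kind="sinusoid",
            params={
                "p0": p0,
                "p1": p1,
                "amplitude": max(amplitude, 0.0),
                "frequency": rng.uniform(1.5, 3.5),
                "phase": rng.uniform(0, 2 * np.pi),
            },
            width_mm=width,
            vessel_class=vessel_class,
            n_samples=64,
        )
        poly = _dense_polyline_px(cspec, shape, pitch)
        if avoid_mask is not None:
            rr = np.clip(np.round(poly[:, 0]).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.round(poly[:, 1]).astype(int), 0, shape[1] - 1)
            if avoid_mask[rr, cc].any():
                continue
        _paint_ribbon(class_mask, poly, width / pitch / 2.0)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a reproducible phantom cohort.

    Eyes alternate OS/OD.  Per eye, per zone and vessel class, the density
    target is the zone target split evenly between arteries and veins, jittered
    by a truncated-normal eye effect, plus any injected group offset; vessels
    are then painted until the target is met.
    """
    rng = np.random.default_rng(spec.seed)
    zones = build_zones(spec.image_shape, spec.pixel_pitch_mm, "OD")
    zones_os = build_zones(spec.image_shape, spec.pixel_pitch_mm, "OS")

    manifest_rows = []
    truth_rows = []
    label_maps: dict[str, VesselLabelMap] = {}
    for gi, group in enumerate(spec.group_names):
        amp = spec.sinusoid_amplitude_mm + spec.amplitude_offsets.get(group, 0.0)
        offsets = spec.density_offsets.get(group, {})
        for ei in range(spec.eyes_per_group):
            eye_id = f"{group}_e{ei:02d}"
            laterality = "OD" if (ei % 2 == 0) else "OS"
            part = zones if laterality == "OD" else zones_os
            artery_mask = np.zeros(spec.image_shape, dtype=bool)
            vein_mask = np.zeros(spec.image_shape, dtype=bool)
            targets: dict[tuple[str, str], float] = {}
            for zone in ANALYSIS_ZONES:
                base = spec.zone_density.get(zone, 0.0) / 2.0
                for cls in ("artery", "vein"):
                    jitter = 1.0 + np.clip(
                        rng.normal(0.0, spec.eye_density_rel_sd), -0.45, 0.45
                    )
                    targets[(zone, cls)] = max(
                        base * jitter + offsets.get((zone, cls), 0.0), 0.0
                    )
            # keep parafoveal vessels clear of the fovea: its small area makes
            # spill-in dominate the realized central density otherwise
            margin_px = int(np.ceil(spec.vessel_width_mm[1] / spec.pixel_pitch_mm / 2)) + 1
            fovea_guard = binary_dilation(part.mask("fovea"), iterations=margin_px)
            # two passes: the second tops up densities eroded by overlap with
            # the other class (junction pixels) or inflated/depleted by spill
            for _ in range(2):
                for zone in ANALYSIS_ZONES:
                    zmask = part.mask(zone)
                    avoid = None if zone == "fovea" else fovea_guard
                    for cls, cmask, omask in (
                        ("artery", artery_mask, vein_mask),
                        ("vein", vein_mask, artery_mask),
                    ):
                        _fill_zone_class(
                            rng, cmask, omask, zmask, targets[(zone, cls)], spec, amp, cls,
                            avoid_mask=avoid,
                        )
            classes = np.zeros(spec.image_shape, dtype=np.uint8)
            classes[artery_mask] = ARTERY
            classes[vein_mask] = VEIN
            classes[artery_mask & vein_mask] = JUNCTION
            if spec.dropout > 0:
                drop = rng.random(spec.image_shape) < spec.dropout
                classes[drop] = BACKGROUND
            # realized densities from the final raster, junction-exclusive for
            # artery/vein so they match the metric convention exactly
            for zone in ANALYSIS_ZONES:
                zmask = part.mask(zone)
                for cls, code in (("artery", ARTERY), ("vein", VEIN)):
                    truth_rows.append(
                        {
                            "eye_id": eye_id,
                            "group": group,
                            "zone": zone,
                            "vessel_class": cls,
                            "target_vd": targets[(zone, cls)],
                            "realized_vd": float((classes[zmask] == code).mean()),
                        }
                    )
            label_maps[eye_id] = VesselLabelMap(
                classes, spec.pixel_pitch_mm, laterality, eye_id
            )
            manifest_rows.append(
                {
                    "eye_id": eye_id,
                    "group": group,
                    "laterality": laterality,
                    "path": f"{eye_id}.png",
                    "pixel_pitch_mm": spec.pixel_pitch_mm,
                }
            )
    return Cohort(
        manifest=pd.DataFrame(manifest_rows),
        label_maps=label_maps,
        truth=pd.DataFrame(truth_rows),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write label maps (indexed PNG), manifest CSV and truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for eye_id, lmap in cohort.label_maps.items():
        write_label_map(lmap, out_dir / f"{eye_id}.png")
    manifest = cohort.manifest.copy()
    manifest["path"] = [str(out_dir / p) for p in manifest["path"]]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    cohort.truth.to_csv(out_dir / "truth.csv", index=False)
    return out_dir / "manifest.csv"
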