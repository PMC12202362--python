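"""Skeletonization and centerline track extraction.

A binary vessel mask is thinned to a one-pixel-wide, topology-preserving
skeleton; the skeleton is decomposed into a graph whose nodes are endpoints
(one skeleton neighbor) and branch points (three or more) and whose edges are
the simple pixel paths between them.  Each edge becomes an ordered
:class:`VesselTrack`, the unit over which the tortuosity metrics are computed.
8-connectivity is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import medial_axis, skeletonize as _sk_skeletonize

from .image_io import ARTERY, JUNCTION, VEIN, VesselLabelMap
from .zones import ZONE_NAMES, ZonePartition

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class VesselTrack:
    """Ordered centerline path (pixel coordinates, row/col)."""

    points: np.ndarray  # (n, 2) int array of (row, col)
    vessel_class: str = "all"  # "artery" | "vein" | "all"
    zone: str = "outside"
    is_loop: bool = False

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SkeletonGraph:
    """Skeleton pixels split into nodes and simple edge paths."""

    skeleton: np.ndarray  # bool raster
    nodes: set[tuple[int, int]]
    edges: list[np.ndarray]  # each (n, 2), endpoints included
    loops: list[np.ndarray] = field(default_factory=list)  # cycles with no node


def skeletonize(mask: np.ndarray, method: str = "zhang") -> np.ndarray:
    """One-pixel-wide topology-preserving skeleton of a binary mask.

    ``method``: "zhang" (default thinning) or "medial_axis".
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    if method == "zhang":
        return _sk_skeletonize(mask)
    if method == "medial_axis":
        return medial_axis(mask)
    raise ValueError(f"unknown skeletonization method {method!r}")


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel.astype(np.uint8), 1)
    counts = np.zeros_like(skel, dtype=np.uint8)
    for dr, dc in _OFFSETS:
        counts += padded[1 + dr : 1 + dr + skel.shape[0], 1 + dc : 1 + dc + skel.shape[1]]
    return counts


def build_graph(skeleton: np.ndarray) -> SkeletonGraph:
    """Decompose a one-pixel skeleton into nodes and simple edge paths.

    Nodes are pixels whose 8-neighbor count differs from 2 (endpoints,
    branch points, isolated pixels).  Edges are traced from each node
    through degree-2 pixels to the next node; every interior pixel belongs
    to exactly one edge.  Pure cycles (components with no node) are cut at
    their lexicographically smallest pixel and flagged as loops.
    """
    skel = np.asarray(skeleton, dtype=bool)
    counts = _neighbor_counts(skel)
    node_mask = skel & (counts != 2)
    nodes = set(zip(*np.nonzero(node_mask)))
    in_skel = lambda r, c: 0 <= r < skel.shape[0] and 0 <= c < skel.shape[1] and skel[r, c]

    visited_inner: set[tuple[int, int]] = set()
    used_node_pairs: set[tuple] = set()
    edges: list[np.ndarray] = []

    def neighbors(p):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in _OFFSETS if in_skel(r + dr, c + dc)]

    for node in sorted(nodes):
        for nb in sorted(neighbors(node)):
            if nb in nodes:
                # direct node-node edge (two points); dedupe by unordered pair
                key = (min(node, nb), max(node, nb))
                if key not in used_node_pairs:
                    used_node_pairs.add(key)
                    edges.append(np.array([node, nb]))
                continue
            if nb in visited_inner:
                continue
            path = [node, nb]
            visited_inner.add(nb)
            prev, cur = node, nb
            while cur not in nodes:
                nxt = [q for q in neighbors(cur) if q != prev]
                # prefer degree-2 continuation; drop already-visited inner px
                nxt = [q for q in nxt if q in nodes or q not in visited_inner]
                if not nxt:
                    break
                # deterministic choice; at most one unvisited continuation on
                # a clean skeleton, but diagonal double-adjacency can give two
                nxt.sort()
                step = next((q for q in nxt if q in nodes), nxt[0])
                path.append(step)
                if step not in nodes:
                    visited_inner.add(step)
                prev, cur = cur, step
            edges.append(np.array(path))

    # pure cycles: skeleton pixels not yet covered
    covered = set(visited_inner) | nodes
    remaining = set(zip(*np.nonzero(skel))) - covered
    loops: list[np.ndarray] = []
    while remaining:
        start = min(remaining)
        path = [start]
        remaining.discard(start)
        prev, cur = None, start
        while True:
            nxt = [q for q in neighbors(cur) if q != prev and q in remaining]
            if not nxt:
                break
            step = min(nxt)
            path.append(step)
            remaining.discard(step)
            prev, cur = cur, step
        loops.append(np.array(path))
    return SkeletonGraph(skeleton=skel, nodes=nodes, edges=edges, loops=loops)


def _majority_class(points: np.ndarray, label_map: VesselLabelMap | None) -> str:
    if label_map is None:
        return "all"
    labels = label_map.classes[points[:, 0], points[:, 1]]
    n_a = int(np.sum(labels == ARTERY))
    n_v = int(np.sum(labels == VEIN))
    if n_a == 0 and n_v == 0:
        return "all"
    return "artery" if n_a >= n_v else "vein"


def _majority_zone(points: np.ndarray, partition: ZonePartition | None) -> str:
    if partition is None:
        return "outside"
    codes = partition.zones[points[:, 0], points[:, 1]]
    vals, cnts = np.unique(codes, return_counts=True)
    top = cnts.max()
    winners = vals[cnts == top]
    if len(winners) == 1:
        return ZONE_NAMES[int(winners[0])]
    return ZONE_NAMES[int(codes[0])]  # tie -> zone of the first point


def extract_tracks(
    graph: SkeletonGraph,
    min_length: int = 11,
    label_map: VesselLabelMap | None = None,
    partition: ZonePartition | None = None,
) -> list[VesselTrack]:
    """Turn graph edges (and cut loops) into attributed vessel tracks.

    Tracks shorter than ``min_length`` points are dropped (they still count
    toward skeleton-based metrics such as VLF, which use the raster, not the
    tracks).  Vessel class is the majority artery/vein label under the track
    (junction pixels are neutral; tie goes to artery, deterministically);
    zone is the majority pixel zone, tie going to the first point's zone.
    """
    tracks: list[VesselTrack] = []
    for path, is_loop in [(e, False) for e in graph.edges] + [(l, True) for l in graph.loops]:
        if len(path) < max(min_length, 2):
            continue
        tracks.append(
            VesselTrack(
                points=np.asarray(path),
                vessel_class=_majority_class(np.asarray(path), label_map),
                zone=_majority_zone(np.asarray(path), partition),
                is_loop=is_loop,
            )
        )
    return tracks


def tracks_to_csv(tracks: list[VesselTrack], path) -> None:
    """Export tracks as audit-friendly polylines (one row per point)."""
    import pandas as pd

    rows = [
        {
            "track_id": i,
            "point_index": j,
            "row_px": int(r),
            "col_px": int(c),
            "vessel_class": t.vessel_class,
            "zone": t.zone,
            "is_loop": t.is_loop,
        }
        for i, t in enumerate(tracks)
        for j, (r, c) in enumerate(t.points)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def tracks_from_mask(
    mask: np.ndarray,
    min_length: int = 11,
    label_map: VesselLabelMap | None = None,
    partition: ZonePartition | None = None,
    method: str = "zhang",
) -> tuple[np.ndarray, list[VesselTrack]]:
    """Convenience: skeletonize a mask and extract its tracks."""
    skel = skeletonize(mask, method=method)
    graph = build_graph(skel)
    return skel, extract_tracks(graph, min_length, label_map, partition)
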