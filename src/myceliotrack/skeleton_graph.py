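"""Skeletonization and conversion of skeletons into hyphal-segment graphs.

A cleaned binary mask is thinned to a single-pixel-wide, topology-preserving
skeleton (Zhang–Suen).  Skeleton pixels with exactly one 8-neighbour are tips,
pixels with three or more are junction pixels; runs of degree-2 pixels between
them are hyphal segments.  Adjacent junction pixels (thinning emits small
blobs at crossings) are merged into a single node at their centroid.  Edge
lengths are the summed pixel-to-pixel distances of the traced chain, corrected
for rasterization staircasing by repeated endpoint-preserving smoothing of the
chain coordinates.

The resulting multigraph (self-loops and parallel edges occur when hyphae
touch) carries, per node: position and kind (tip / junction / isolated), and
per edge: the ordered pixel path plus raw and smoothed lengths in µm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import skeletonize as _skimage_skeletonize

from .segmentation import BinaryMask

_NEIGHBOUR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Skeleton:
    """Single-pixel-wide boolean raster produced by thinning."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)

    def neighbour_counts(self) -> np.ndarray:
        return ndi.convolve(
            self.pixels.astype(int), _NEIGHBOUR_KERNEL, mode="constant", cval=0
        )


@dataclass
class SkeletonGraph:
    """Per-frame graph of tips/junctions (nodes) and hyphal segments (edges).

    graph nodes carry: pos (row, col) float, kind in {tip, junction, isolated},
    pixels (tuple of raster pixels merged into the node).
    graph edges carry: path (ordered (N, 2) pixel array, endpoints included),
    raw_length_um, length_um (smoothed).
    """

    graph: nx.MultiGraph
    frame_index: int
    calibration: float

    @property
    def tips(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "tip"]

    @property
    def junctions(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "junction"]

    def node_position_um(self, node: int) -> np.ndarray:
        return np.asarray(self.graph.nodes[node]["pos"]) * self.calibration

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for _, _, d in self.graph.edges(data=True)))


def skeletonize(mask: BinaryMask | np.ndarray) -> Skeleton:
    """Thin a cleaned mask to a single-pixel skeleton (Zhang–Suen)."""
    if isinstance(mask, BinaryMask):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return Skeleton(np.zeros(mask.shape, dtype=bool))
    return Skeleton(_skimage_skeletonize(mask, method="zhang"))


def prune_skeleton(
    skeleton: Skeleton, calibration: float, min_spur_um: float = 1.5
) -> Skeleton:
    """Remove terminal spurs shorter than ``min_spur_um`` from a skeleton.

    A spur is a chain from a tip pixel to a junction pixel; short spurs are
    noise pixels that attached to a filament during mask cleaning.  Whole
    isolated segments (tip-to-tip chains, e.g. an unbranched germ tube) are
    never pruned.  Pruning iterates until stable, since removing a spur can
    turn a junction into a regular chain pixel.
    """
    px = skeleton.pixels.copy()
    if min_spur_um <= 0 or not px.any():
        return Skeleton(px)
    min_px_len = min_spur_um / calibration
    changed = True
    while changed:
        changed = False
        counts = ndi.convolve(px.astype(int), _NEIGHBOUR_KERNEL,
                              mode="constant", cval=0)
        fg = set(zip(*np.nonzero(px)))

        def neighbours(p):
            r, c = p
            return [(r + dr, c + dc) for dr, dc in _OFFSETS
                    if (r + dr, c + dc) in fg]

        tips = sorted(p for p in fg if counts[p] == 1)
        for tip in tips:
            if not px[tip]:
                continue
            chain = [tip]
            prev, cur = None, tip
            reached_junction = False
            while True:
                nbrs = [q for q in neighbours(cur) if q != prev and px[q]]
                if not nbrs:
                    break
                nxt = nbrs[0]
                if counts[nxt] >= 3:
                    reached_junction = True
                    break
                chain.append(nxt)
                prev, cur = cur, nxt
                if counts[cur] == 1:  # other end is a tip: isolated segment
                    break
            if reached_junction:
                length = path_length(np.asarray(chain, dtype=float))
                if length < min_px_len:
                    for p in chain:
                        px[p] = False
                    changed = True
        if changed:
            continue
    if px.any():
        # removing a spur can leave a redundant bump at the old junction;
        # one more thinning pass restores a clean single-pixel skeleton
        px = _skimage_skeletonize(px, method="zhang")
    return Skeleton(px)


def smooth_path(path: np.ndarray, iterations: int = 5) -> np.ndarray:
    """Endpoint-preserving repeated 3-point moving average of path coordinates."""
    coords = np.asarray(path, dtype=np.float64)
    if len(coords) < 3 or iterations <= 0:
        return coords
    out = coords.copy()
    for _ in range(iterations):
        out[1:-1] = (out[:-2] + out[1:-1] + out[2:]) / 3.0
    return out


def path_length(path: np.ndarray, calibration: float = 1.0) -> float:
    """Sum of consecutive Euclidean distances along a path, in µm."""
    coords = np.asarray(path, dtype=np.float64)
    if len(coords) < 2:
        return 0.0
    steps = np.diff(coords, axis=0)
    return float(np.sqrt((steps ** 2).sum(axis=1)).sum() * calibration)


def smooth_path_length(
    path: np.ndarray, calibration: float = 1.0, iterations: int = 5
) -> float:
    """Length of the smoothed path; corrects staircase overestimation."""
    return path_length(smooth_path(path, iterations), calibration)


def _trace_chain(start, first, chain_pixels, neighbours):
    """Follow a run of degree-2 pixels from a node pixel until the next node."""
    path = [start, first]
    prev, cur = start, first
    while cur in chain_pixels:
        nxt = None
        for q in neighbours(cur):
            if q != prev:
                nxt = q
                break
        if nxt is None:  # dead end inside a chain: treat last pixel as endpoint
            break
        path.append(nxt)
        prev, cur = cur, nxt
    return path


def build_graph(
    skeleton: Skeleton,
    calibration: float,
    frame_index: int = 0,
    smoothing_iterations: int = 5,
) -> SkeletonGraph:
    """Convert a skeleton raster into a graph of tips, junctions and segments.

    Node pixels are skeleton pixels with 8-neighbour count 1 (tip) or >= 3
    (junction); adjacent junction pixels merge into one node.  Edges are traced
    pixel-wise through degree-2 chains.  Components consisting of a pure cycle
    (no node pixel) get an anchor node at their lexicographically smallest
    pixel.  Junction–junction edges shorter than 2 px are contracted.
    """
    sk = skeleton.pixels
    G = nx.MultiGraph()
    if not sk.any():
        return SkeletonGraph(G, frame_index, calibration)

    counts = skeleton.neighbour_counts()
    fg = set(zip(*np.nonzero(sk)))

    def neighbours(p):
        r, c = p
        return [
            (r + dr, c + dc)
            for dr, dc in _OFFSETS
            if (r + dr, c + dc) in fg
        ]

    tip_pixels = {p for p in fg if counts[p] == 1}
    junction_pixels = {p for p in fg if counts[p] >= 3}
    isolated_pixels = {p for p in fg if counts[p] == 0}
    chain_pixels = fg - tip_pixels - junction_pixels - isolated_pixels

    # cluster adjacent junction pixels into single nodes
    pixel_to_cluster: dict[tuple[int, int], int] = {}
    clusters: list[list[tuple[int, int]]] = []
    if junction_pixels:
        jmask = np.zeros(sk.shape, dtype=bool)
        rows, cols = zip(*junction_pixels)
        jmask[rows, cols] = True
        labels, n_lab = ndi.label(jmask, structure=np.ones((3, 3), int))
        for lab in range(1, n_lab + 1):
            pts = sorted(zip(*np.nonzero(labels == lab)))
            pts = [(int(r), int(c)) for r, c in pts]
            idx = len(clusters)
            clusters.append(pts)
            for p in pts:
                pixel_to_cluster[p] = idx

    node_id = 0
    pixel_to_node: dict[tuple[int, int], int] = {}

    def add_node(pixels: list[tuple[int, int]], kind: str) -> int:
        nonlocal node_id
        arr = np.asarray(pixels, dtype=float)
        pos = tuple(arr.mean(axis=0))
        nid = node_id
        node_id += 1
        G.add_node(nid, pos=pos, kind=kind, pixels=tuple(sorted(pixels)))
        for p in pixels:
            pixel_to_node[p] = nid
        return nid

    for p in sorted(isolated_pixels):
        add_node([p], "isolated")
    for p in sorted(tip_pixels):
        add_node([p], "tip")
    for pts in clusters:
        add_node(pts, "junction")

    def add_edge(path: list[tuple[int, int]]):
        u = pixel_to_node[path[0]]
        v = pixel_to_node[path[-1]]
        arr = np.asarray(path, dtype=float)
        raw = path_length(arr, calibration)
        smoothed = smooth_path_length(arr, calibration, smoothing_iterations)
        G.add_edge(u, v, path=np.asarray(path, dtype=np.int32),
                   raw_length_um=raw, length_um=smoothed)

    node_pixels = sorted(tip_pixels) + sorted(junction_pixels)
    visited_chain: set[tuple[int, int]] = set()
    seen_direct: set[frozenset] = set()

    for p in node_pixels:
        for q in neighbours(p):
            if q in chain_pixels:
                if q in visited_chain:
                    continue
                path = _trace_chain(p, q, chain_pixels, neighbours)
                visited_chain.update(pt for pt in path if pt in chain_pixels)
                if path[-1] in chain_pixels:
                    # chain ended without reaching a node pixel (should not
                    # happen on valid skeletons); make the end a tip node
                    add_node([path[-1]], "tip")
                    tip_pixels.add(path[-1])
                add_edge(path)
            elif q in tip_pixels or q in junction_pixels:
                # direct node-node adjacency
                same_cluster = (
                    p in junction_pixels
                    and q in junction_pixels
                    and pixel_to_cluster[p] == pixel_to_cluster[q]
                )
                if same_cluster:
                    continue
                key = frozenset((p, q))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                add_edge([p, q])

    # pure cycles: components of chain pixels never reached from a node
    remaining = sorted(chain_pixels - visited_chain)
    while remaining:
        start = remaining[0]
        anchor = add_node([start], "junction")
        first = neighbours(start)[0]
        loop_chain = chain_pixels - {start}
        path = _trace_chain(start, first, loop_chain, neighbours)
        if path[-1] != start:
            path.append(start)
        visited_chain.update(pt for pt in path if pt in chain_pixels)
        add_edge(path)
        remaining = sorted(chain_pixels - visited_chain)

    _contract_short_junction_edges(G, calibration)
    _relabel_sorted(G)
    return SkeletonGraph(G, frame_index, calibration)


def _contract_short_junction_edges(G: nx.MultiGraph, calibration: float) -> None:
    """Merge junction pairs connected by an edge shorter than 2 px (artifacts)."""
    while True:
        target = None
        for u, v, k, d in G.edges(keys=True, data=True):
            if u == v:
                continue
            if (
                G.nodes[u]["kind"] == "junction"
                and G.nodes[v]["kind"] == "junction"
                and d["raw_length_um"] / calibration < 2.0
            ):
                target = (u, v, k)
                break
        if target is None:
            return
        u, v, k = target
        pixels = tuple(sorted(set(G.nodes[u]["pixels"]) | set(G.nodes[v]["pixels"])))
        arr = np.asarray(pixels, dtype=float)
        G.remove_edge(u, v, key=k)
        # reattach v's edges to u
        for _, w, d in list(G.edges(v, data=True)):
            w2 = u if w == v else w
            G.add_edge(u, w2, **d)
        G.remove_node(v)
        G.nodes[u]["pixels"] = pixels
        G.nodes[u]["pos"] = tuple(arr.mean(axis=0))


def _relabel_sorted(G: nx.MultiGraph) -> None:
    """Assign node ids 0..n-1 ordered by (row, col) position for determinism."""
    order = sorted(G.nodes, key=lambda n: (G.nodes[n]["pos"], n))
    mapping = {old: new for new, old in enumerate(order)}
    H = nx.relabel_nodes(G, mapping, copy=True)
    G.clear()
    G.update(H)


def to_graphml(sg: SkeletonGraph) -> str:
    """Serialize a skeleton graph to GraphML (positions in µm)."""
    H = nx.MultiGraph()
    for n, d in sg.graph.nodes(data=True):
        H.add_node(
            n,
            kind=d["kind"],
            x_um=float(d["pos"][1] * sg.calibration),
            y_um=float(d["pos"][0] * sg.calibration),
        )
    for u, v, d in sg.graph.edges(data=True):
        H.add_edge(u, v, length_um=float(d["length_um"]),
                   raw_length_um=float(d["raw_length_um"]))
    buf = io.BytesIO()
    nx.write_graphml(H, buf)
    return buf.getvalue().decode("utf-8")
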