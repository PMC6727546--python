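"""Frame-to-frame node matching and per-hypha track assembly.

Junctions of the mycelial graph are spatially stationary under planar growth,
so they are matched between consecutive frames by nearest-neighbour search
within a small radius.  Tips move forward as hyphae elongate and get a larger
search radius.  Matching is greedy, ordered by ascending displacement, and
one-to-one; it never bridges gaps — a missed detection ends a track.

A hypha track follows one tip from its first appearance.  Per frame it records
the graph path from a stable anchor (the nearest matched junction at track
birth, or the far end of the component for an unbranched germ tube) to the
tip; the hypha length is the summed smoothed edge length along that path.
Sanity checks exclude tracks whose anchor and tip fall into different
connected components (lost connectivity) or whose length drops by more than a
tolerance between frames (a "shortcut" created when adjacent hyphae merge in
the mask); excluded tracks are truncated at the last valid frame but retained
with their status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .skeleton_graph import SkeletonGraph

STATUS_ACTIVE = "active"
STATUS_ENDED = "ended"
STATUS_SHORTCUT = "excluded-shortcut"
STATUS_DISCONNECTED = "excluded-disconnected"


@dataclass(frozen=True)
class NodeMatch:
    """A one-to-one correspondence between nodes of consecutive frames."""

    node_t: int
    node_t1: int
    displacement_um: float
    kind: str


@dataclass
class TrackRecord:
    """State of one hypha in one frame."""

    frame: int
    tip_node: int
    anchor_node: int
    path_nodes: tuple[int, ...]
    hop_count: int
    length_um: float
    tip_pos_um: tuple[float, float]


@dataclass
class HyphaTrack:
    """One tip followed through consecutive frames."""

    track_id: int
    records: list[TrackRecord] = field(default_factory=list)
    status: str = STATUS_ACTIVE
    end_reason: str = ""
    flagged_short: bool = False     # fewer time points than needed for fits
    flagged_spurious: bool = False  # never exceeds the minimum hypha length

    @property
    def frames(self) -> list[int]:
        return [r.frame for r in self.records]

    @property
    def lengths_um(self) -> np.ndarray:
        return np.asarray([r.length_um for r in self.records])

    @property
    def excluded(self) -> bool:
        return self.status in (STATUS_SHORTCUT, STATUS_DISCONNECTED)

    def eligible_for_fits(self) -> bool:
        return not self.excluded and not self.flagged_short and not self.flagged_spurious

    def tip_travel_um(self) -> float:
        pos = np.asarray([r.tip_pos_um for r in self.records])
        if len(pos) < 2:
            return 0.0
        return float(np.sqrt((np.diff(pos, axis=0) ** 2).sum(axis=1)).sum())


def match_nodes(
    g_t: SkeletonGraph,
    g_t1: SkeletonGraph,
    junction_radius_um: float = 2.0,
    tip_radius_um: float = 10.0,
) -> list[NodeMatch]:
    """Greedy one-to-one matching of same-kind nodes between two frames.

    Candidate pairs within the kind-specific radius are sorted by ascending
    displacement (ties: ascending node ids) and accepted while both endpoints
    are unmatched.
    """
    if not (tip_radius_um >= junction_radius_um > 0):
        raise ValueError("require tip_radius >= junction_radius > 0")
    matches: list[NodeMatch] = []
    for kind, radius in (("junction", junction_radius_um), ("tip", tip_radius_um)):
        a = [n for n in g_t.graph.nodes if g_t.graph.nodes[n]["kind"] == kind]
        b = [n for n in g_t1.graph.nodes if g_t1.graph.nodes[n]["kind"] == kind]
        if not a or not b:
            continue
        pa = np.asarray([g_t.node_position_um(n) for n in a])
        pb = np.asarray([g_t1.node_position_um(n) for n in b])
        d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
        candidates = [
            (d[i, j], a[i], b[j])
            for i in range(len(a))
            for j in range(len(b))
            if d[i, j] <= radius
        ]
        candidates.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for dist, na, nb in candidates:
            if na in used_a or nb in used_b:
                continue
            used_a.add(na)
            used_b.add(nb)
            matches.append(NodeMatch(na, nb, float(dist), kind))
    return matches


def _forward_maps(matches_per_pair: Sequence[Sequence[NodeMatch]]):
    return [{m.node_t: m.node_t1 for m in ms} for ms in matches_per_pair]


def _component_nodes(G: nx.MultiGraph, node: int) -> set[int]:
    return nx.node_connected_component(G, node)


def _geodesic(G: nx.MultiGraph, a: int, b: int):
    """Shortest path by smoothed edge length; None if disconnected."""
    try:
        length, path = nx.single_source_dijkstra(G, a, b, weight="length_um")
    except nx.NetworkXNoPath:
        return None
    return float(length), tuple(path)


def _choose_anchor(g: SkeletonGraph, tip: int, next_forward: dict[int, int]):
    """Anchor for a newborn track: nearest junction (prefer ones matched into
    the next frame); for a junction-free component, the farthest node."""
    G = g.graph
    comp = _component_nodes(G, tip)
    junctions = [n for n in comp if G.nodes[n]["kind"] == "junction" and n != tip]
    dist = nx.single_source_dijkstra_path_length(G, tip, weight="length_um")
    if junctions:
        stable = [n for n in junctions if n in next_forward]
        pool = stable or junctions
        return min(pool, key=lambda n: (dist.get(n, np.inf), n))
    others = [n for n in comp if n != tip and G.nodes[n]["kind"] != "isolated"]
    if not others:
        return None
    return max(others, key=lambda n: (dist.get(n, -np.inf), -n))


def assemble_tracks(
    graphs: Sequence[SkeletonGraph],
    matches_per_pair: Sequence[Sequence[NodeMatch]],
) -> list[HyphaTrack]:
    """Build hypha tracks from per-frame graphs and consecutive-pair matches.

    A track starts at every tip that is not the continuation of a previous
    frame's tip, and advances while both its tip and its anchor are matched
    into the next frame.  Mirror tracks of unbranched hyphae (both free ends
    are degree-1 nodes following the same pixel path) are deduplicated keeping
    the end that travels farther — the growing tip.
    """
    if len(matches_per_pair) != max(len(graphs) - 1, 0):
        raise ValueError("need one match set per consecutive frame pair")
    forward = _forward_maps(matches_per_pair)
    n_frames = len(graphs)
    continued: list[set[int]] = [set() for _ in range(n_frames)]
    tracks: list[HyphaTrack] = []

    for f0 in range(n_frames):
        g0 = graphs[f0]
        for tip in sorted(g0.tips):
            if tip in continued[f0]:
                continue
            track = HyphaTrack(track_id=len(tracks))
            fwd0 = forward[f0] if f0 < n_frames - 1 else {}
            anchor = _choose_anchor(g0, tip, fwd0)
            if anchor is None:
                continue
            cur_tip, cur_anchor = tip, anchor
            f = f0
            while True:
                g = graphs[f]
                geo = _geodesic(g.graph, cur_anchor, cur_tip)
                if geo is None:
                    track.end_reason = "disconnected"
                    break
                length, path = geo
                track.records.append(
                    TrackRecord(
                        frame=f,
                        tip_node=cur_tip,
                        anchor_node=cur_anchor,
                        path_nodes=path,
                        hop_count=len(path) - 1,
                        length_um=length,
                        tip_pos_um=tuple(g.node_position_um(cur_tip)),
                    )
                )
                if f == n_frames - 1:
                    track.end_reason = "end-of-stack"
                    break
                fwd = forward[f]
                if cur_tip not in fwd:
                    track.end_reason = "tip-unmatched"
                    break
                next_tip = fwd[cur_tip]
                if cur_anchor not in fwd:
                    track.end_reason = "anchor-unmatched"
                    break
                cur_tip, cur_anchor = next_tip, fwd[cur_anchor]
                f += 1
                continued[f].add(cur_tip)
            if track.records:
                tracks.append(track)

    return _deduplicate_mirrors(tracks)


def _deduplicate_mirrors(tracks: list[HyphaTrack]) -> list[HyphaTrack]:
    """Drop the lesser of two tracks tracing the same path with swapped ends."""
    drop: set[int] = set()
    by_start: dict[tuple, list[HyphaTrack]] = {}
    for t in tracks:
        key = (t.records[0].frame, len(t.records))
        by_start.setdefault(key, []).append(t)
    for group in by_start.values():
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if a.track_id in drop or b.track_id in drop:
                    continue
                mirrored = all(
                    ra.tip_node == rb.anchor_node
                    and ra.anchor_node == rb.tip_node
                    and ra.path_nodes == tuple(reversed(rb.path_nodes))
                    for ra, rb in zip(a.records, b.records)
                )
                if mirrored:
                    loser = a if a.tip_travel_um() < b.tip_travel_um() else b
                    drop.add(loser.track_id)
    kept = [t for t in tracks if t.track_id not in drop]
    for new_id, t in enumerate(kept):
        t.track_id = new_id
    return kept


def sanity_filter(
    track: HyphaTrack,
    graphs: Sequence[SkeletonGraph],
    shortcut_abs_um: float = 1.0,
    shortcut_rel: float = 0.10,
    min_track_points: int = 3,
    min_track_length_um: float = 2.0,
) -> HyphaTrack:
    """Apply connectivity and shortcut checks; truncate and set status.

    A length decrease between consecutive frames larger than
    ``max(shortcut_abs_um, shortcut_rel * current_length)`` indicates a merged
    adjacent hypha providing a shorter graph path; the track is truncated at
    the last valid frame.  Tracks that lost anchor–tip connectivity are marked
    excluded-disconnected.  Short tracks and tracks that never reach
    ``min_track_length_um`` are flagged (kept, but not used for rate fits).
    """
    if track.end_reason == "disconnected":
        track.status = STATUS_DISCONNECTED
    for i in range(1, len(track.records)):
        prev = track.records[i - 1].length_um
        cur = track.records[i].length_um
        tolerance = max(shortcut_abs_um, shortcut_rel * prev)
        if prev - cur > tolerance:
            track.records = track.records[:i]
            track.status = STATUS_SHORTCUT
            track.end_reason = "shortcut"
            break
    if track.status == STATUS_ACTIVE and track.end_reason != "end-of-stack":
        track.status = STATUS_ENDED
    track.flagged_short = len(track.records) < min_track_points
    track.flagged_spurious = (
        float(track.lengths_um.max(initial=0.0)) < min_track_length_um
    )
    return track


def track_stack(
    graphs: Sequence[SkeletonGraph],
    junction_radius_um: float = 2.0,
    tip_radius_um: float = 10.0,
    shortcut_abs_um: float = 1.0,
    shortcut_rel: float = 0.10,
    min_track_points: int = 3,
    min_track_length_um: float = 2.0,
) -> list[HyphaTrack]:
    """Match all consecutive frame pairs, assemble tracks, apply sanity checks."""
    matches = [
        match_nodes(graphs[i], graphs[i + 1], junction_radius_um, tip_radius_um)
        for i in range(len(graphs) - 1)
    ]
    tracks = assemble_tracks(graphs, matches)
    return [
        sanity_filter(
            t, graphs, shortcut_abs_um, shortcut_rel,
            min_track_points, min_track_length_um,
        )
        for t in tracks
    ]
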