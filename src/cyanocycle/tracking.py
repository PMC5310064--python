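"""Lineage tracking and temporal correction of cluster classifications.

Connected components are linked frame to frame by mask overlap with a
nearest-centroid fallback.  Along each component track, the per-frame
singlet/doublet/multiplet posteriors are smoothed by a dynamic program
that only allows the apparent cell count to increase with time — a track
may progress singlet → doublet but never fall back, mirroring the fact
that cells divide and do not fuse.  A division event is placed at the
first frame of the stable doublet labeling (or at the physical component
split if the doublet phase was never seen), with an uncertainty equal to
half the dwell between the last confident singlet frame and the first
confident doublet frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import itertools
import math

import numpy as np
import networkx as nx

from .geometry import Contour
from .growth import GrowthCurve
from .schedule import IlluminationSchedule
from .segmentation import (Cluster, MorphologyModel, extract_clusters,
                           segment_binary, split_cluster)

__all__ = [
    "TrackedCell",
    "track_and_correct",
    "process_stack",
    "volumes_from_tracks",
]

@dataclass
class TrackedCell:
    """One reconstructed cell: per-frame contours plus lineage links."""

    cell_id: int
    contours: dict = field(default_factory=dict)   # frame -> Contour
    birth_frame: Optional[int] = None              # None for founders
    division_frame: Optional[int] = None
    parent_id: Optional[int] = None
    sister_id: Optional[int] = None
    division_time_uncertainty: float = float("nan")
    flags: list = field(default_factory=list)

    @property
    def frames(self) -> list:
        return sorted(self.contours)


# --------------------------------------------------------------------------- #
# component linking
# --------------------------------------------------------------------------- #

def _pixel_set(cluster: Cluster) -> set:
    return {(int(r), int(c)) for r, c in cluster.coords}


def _link_frames(prev: list, curr: list, max_move_um: float) -> dict:
    """Map each current cluster index to a parent cluster index in the
    previous frame (or None).  Overlap wins; otherwise nearest centroid
    within the gate."""
    prev_sets = [_pixel_set(c) for c in prev]
    links = {}
    for j, c in enumerate(curr):
        cset = _pixel_set(c)
        overlaps = [len(cset & ps) for ps in prev_sets]
        if overlaps and max(overlaps) > 0:
            links[j] = int(np.argmax(overlaps))
            continue
        best, best_d = None, max_move_um
        for i, p in enumerate(prev):
            d = math.hypot(c.centroid[0] - p.centroid[0],
                           c.centroid[1] - p.centroid[1])
            if d < best_d:
                best, best_d = i, d
        links[j] = best
    return links


def _monotone_labels(posteriors: list) -> list:
    """Maximum-posterior class path with non-decreasing cell count."""
    if not posteriors:
        return []
    classes = ("singlet", "doublet", "multiplet")
    NEG = -1e18
    n = len(posteriors)
    logp = np.array([[math.log(max(p[c], 1e-12)) for c in classes]
                     for p in posteriors])
    dp = np.full((n, 3), NEG)
    back = np.zeros((n, 3), int)
    dp[0] = logp[0]
    for t in range(1, n):
        for s in range(3):
            prev_best = int(np.argmax(dp[t - 1, :s + 1]))
            dp[t, s] = dp[t - 1, prev_best] + logp[t, s]
            back[t, s] = prev_best
    path = [int(np.argmax(dp[-1]))]
    for t in range(n - 1, 0, -1):
        path.append(back[t, path[-1]])
    path.reverse()
    return [classes[s] for s in path]


class _ComponentTrack:
    """Chain of linked clusters (one component through time)."""

    _ids = itertools.count()

    def __init__(self):
        self.id = next(self._ids)
        self.frames: list = []        # frame indices
        self.clusters: list = []      # Cluster per frame
        self.children: list = []      # component tracks after a split
        self.parent: Optional["_ComponentTrack"] = None
        self.lost = False
        self.merged = False

    def add(self, frame: int, cluster: Cluster):
        self.frames.append(frame)
        self.clusters.append(cluster)


def _build_component_tracks(frame_clusters: list,
                            max_move_um: float,
                            max_gap: int = 3) -> list:
    """Assemble component tracks and split/merge structure."""
    tracks: list[_ComponentTrack] = []
    active: dict = {}   # cluster index in previous frame -> track
    prev = []
    for f, clusters in enumerate(frame_clusters):
        links = _link_frames(prev, clusters, max_move_um) if prev else \
            {j: None for j in range(len(clusters))}
        by_parent: dict = {}
        for j, i in links.items():
            by_parent.setdefault(i, []).append(j)
        new_active = {}
        for i, js in by_parent.items():
            if i is None or i not in active:
                for j in js:   # appearing component(s): new root track(s)
                    tr = _ComponentTrack()
                    tr.add(f, clusters[j])
                    tracks.append(tr)
                    new_active[j] = tr
            elif len(js) == 1:
                tr = active[i]
                tr.add(f, clusters[js[0]])
                new_active[js[0]] = tr
            else:
                # split: close the parent component, open children
                parent_tr = active[i]
                js_sorted = sorted(
                    js, key=lambda j: -len(clusters[j].coords))[:2]
                for j in js_sorted:
                    child = _ComponentTrack()
                    child.parent = parent_tr
                    child.add(f, clusters[j])
                    parent_tr.children.append(child)
                    tracks.append(child)
                    new_active[j] = child
                for j in js:
                    if j not in js_sorted:
                        tr = _ComponentTrack()
                        tr.add(f, clusters[j])
                        tracks.append(tr)
                        new_active[j] = tr
        surviving = {id(t) for t in new_active.values()}
        for i, tr in active.items():
            if id(tr) in surviving or tr.children:
                continue
            tr.lost = True
            # merge check: last centroid near a current component
            last = tr.clusters[-1].centroid
            for j, cl in enumerate(clusters):
                d = math.hypot(last[0] - cl.centroid[0],
                               last[1] - cl.centroid[1])
                if d < 1.0 and j in new_active:
                    new_active[j].merged = True
                    tr.merged = True
        active = new_active
        prev = clusters
    return tracks


# --------------------------------------------------------------------------- #
# cell assembly
# --------------------------------------------------------------------------- #

def track_and_correct(frame_clusters: Sequence[Sequence[Cluster]],
                      frame_interval: float = 1.0 / 6.0,
                      max_move_um: float = 2.5) -> tuple:
    """Reconstruct single cells and their lineage from per-frame clusters.

    ``frame_clusters`` holds, per frame, the classified clusters (with
    posteriors).  Returns ``(tracked_cells, lineage)`` where ``lineage``
    is a directed graph of cell ids (edges mother → daughter).

    Within each component track the class labels are smoothed to the
    maximum-posterior monotone (non-decreasing cell count) sequence; the
    division is stamped at the first stable doublet frame and the doublet
    is decomposed into two contours per frame by the two-ellipse fit.
    Daughter identity is carried across frames (and across the physical
    split of the component) by centroid continuity.  Multiplet clusters
    close the affected tracks and flag them, excluding those cells from
    downstream cycle statistics.
    """
    if len(frame_clusters) < 2:
        raise ValueError("need at least 2 frames to track")
    comp_tracks = _build_component_tracks(list(frame_clusters), max_move_um)

    cells: dict = {}
    lineage = nx.DiGraph()
    next_cell_id = itertools.count()

    roots = [tr for tr in comp_tracks if tr.parent is None and
             tr.frames and tr.frames[0] == 0]
    orphans = [tr for tr in comp_tracks if tr.parent is None and
               tr.frames and tr.frames[0] != 0]

    def new_cell(parent_id=None, sister_id=None, birth_frame=None):
        cid = next(next_cell_id)
        cell = TrackedCell(cell_id=cid, parent_id=parent_id,
                           sister_id=sister_id, birth_frame=birth_frame)
        cells[cid] = cell
        lineage.add_node(cid)
        if parent_id is not None:
            lineage.add_edge(parent_id, cid)
        return cell

    def process(track: _ComponentTrack, owner: TrackedCell):
        if track.merged:
            # two tracks collided into one component: ambiguous, exclude
            for i in range(len(track.frames)):
                contour, _, _ = _single_contour(track.clusters[i])
                owner.contours[track.frames[i]] = contour
            owner.flags.append("merge")
            return
        labels = _monotone_labels([c.posterior for c in track.clusters])
        # first frame of stable doublet labeling
        div_idx = next((i for i, l in enumerate(labels) if l == "doublet"),
                       None)
        multi_idx = next((i for i, l in enumerate(labels)
                          if l == "multiplet"), None)
        if multi_idx is not None and (div_idx is None or multi_idx <= div_idx):
            # ambiguous clump: contour what we can, then close and flag
            for i in range(multi_idx):
                contour, _, _ = _single_contour(track.clusters[i])
                owner.contours[track.frames[i]] = contour
            owner.flags.append("multiplet")
            return

        end = div_idx if div_idx is not None else len(labels)
        for i in range(end):
            contour, _, _ = _single_contour(track.clusters[i])
            owner.contours[track.frames[i]] = contour

        if div_idx is None:
            if track.children:
                # physical split without a detected doublet phase
                split_frame = track.children[0].frames[0]
                _start_daughters(track, owner, split_frame, None)
            elif track.lost:
                owner.flags.append("lost")
            return

        # division detected within the component
        div_frame = track.frames[div_idx]
        owner.division_frame = div_frame
        owner.division_time_uncertainty = _division_uncertainty(
            track, labels, div_idx, frame_interval)
        daughter_contours = _split_doublet_phase(track, div_idx)
        _start_daughters(track, owner, div_frame, daughter_contours)

    def _start_daughters(track, owner, div_frame, daughter_contours,
                         **_ignored):
        d1 = new_cell(parent_id=owner.cell_id, birth_frame=div_frame)
        d2 = new_cell(parent_id=owner.cell_id, birth_frame=div_frame)
        d1.sister_id, d2.sister_id = d2.cell_id, d1.cell_id
        if owner.division_frame is None:
            owner.division_frame = div_frame
            owner.division_time_uncertainty = 0.5 * frame_interval
        if daughter_contours:
            for f, (c1, c2) in daughter_contours.items():
                d1.contours[f] = c1
                d2.contours[f] = c2
        # continue into child component tracks, matched by centroid
        if track.children:
            refs = [_last_centroid(d) for d in (d1, d2)]
            child_cents = [tr.clusters[0].centroid for tr in track.children]
            if None not in refs and len(track.children) == 2:
                d00 = _dist(refs[0], child_cents[0]) + _dist(refs[1],
                                                             child_cents[1])
                d01 = _dist(refs[0], child_cents[1]) + _dist(refs[1],
                                                             child_cents[0])
                order = (0, 1) if d00 <= d01 else (1, 0)
            else:
                order = tuple(range(len(track.children)))
            for d, idx in zip((d1, d2), order):
                if idx < len(track.children):
                    process(track.children[idx], d)

    for tr in roots:
        process(tr, new_cell())
    for tr in orphans:
        cell = new_cell()
        cell.flags.append("appeared")
        process(tr, cell)

    return list(cells.values()), lineage


def _dist(p, q) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _last_centroid(cell: TrackedCell):
    if not cell.contours:
        return None
    f = max(cell.contours)
    pts = cell.contours[f].points
    return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def _single_contour(cluster: Cluster):
    contours, resid, low_conf = split_cluster(cluster, 1)
    return contours[0], resid, low_conf


def _split_doublet_phase(track: _ComponentTrack, div_idx: int) -> dict:
    """Two contours per doublet frame, identities carried by centroid
    continuity."""
    out: dict = {}
    prev_centroids = None
    for i in range(div_idx, len(track.frames)):
        contours, resid, low_conf = split_cluster(track.clusters[i], 2)
        cents = [(float(c.points[:, 0].mean()), float(c.points[:, 1].mean()))
                 for c in contours]
        if prev_centroids is not None:
            d_keep = (_dist(cents[0], prev_centroids[0])
                      + _dist(cents[1], prev_centroids[1]))
            d_swap = (_dist(cents[1], prev_centroids[0])
                      + _dist(cents[0], prev_centroids[1]))
            if d_swap < d_keep:
                contours = contours[::-1]
                cents = cents[::-1]
        out[track.frames[i]] = tuple(contours)
        prev_centroids = cents
    return out


def _division_uncertainty(track, labels, div_idx, frame_interval) -> float:
    post = [c.posterior for c in track.clusters]
    last_singlet = None
    for i in range(div_idx - 1, -1, -1):
        if post[i] and max(post[i], key=post[i].get) == "singlet":
            last_singlet = i
            break
    first_doublet = None
    for i in range(div_idx, len(labels)):
        if post[i] and max(post[i], key=post[i].get) == "doublet":
            first_doublet = i
            break
    if last_singlet is None or first_doublet is None:
        return 0.5 * frame_interval
    dwell = (track.frames[first_doublet] - track.frames[last_singlet])
    return 0.5 * max(dwell, 1) * frame_interval


# --------------------------------------------------------------------------- #
# stack-level convenience
# --------------------------------------------------------------------------- #

def process_stack(stack: np.ndarray, pixel_size: float,
                  model: MorphologyModel,
                  frame_interval: float = 1.0 / 6.0,
                  max_move_um: float = 2.5) -> tuple:
    """Segment, classify and track a whole image stack.

    Returns ``(tracked_cells, lineage, frame_clusters)``.
    """
    frame_clusters = []
    for f, img in enumerate(stack):
        mask, offsets = segment_binary(img, pixel_size, return_offsets=True)
        frame_clusters.append(extract_clusters(mask, pixel_size,
                                               frame_index=f, model=model,
                                               offsets=offsets, image=img))
    tracked, lineage = track_and_correct(frame_clusters, frame_interval,
                                         max_move_um)
    return tracked, lineage, frame_clusters


def volumes_from_tracks(tracked: Sequence[TrackedCell],
                        frame_times: np.ndarray,
                        schedule: Optional[IlluminationSchedule] = None,
                        n_slices: int = 100,
                        smooth_window: int = 3) -> dict:
    """Per-cell volume curves from tracked contours (disk integration).

    A short running-median (``smooth_window`` frames, default 3) damps
    frame-to-frame fitting jitter before any parameter read-off; set 1 to
    disable."""
    from scipy.ndimage import median_filter

    from .geometry import contour_volume
    curves = {}
    for cell in tracked:
        frames = cell.frames
        if len(frames) < 2:
            continue
        times = np.array([frame_times[f] for f in frames])
        vols = np.array([contour_volume(cell.contours[f], n_slices=n_slices)
                         for f in frames])
        if smooth_window > 1 and len(vols) >= smooth_window:
            vols = median_filter(vols, size=smooth_window, mode="nearest")
        curves[cell.cell_id] = GrowthCurve(cell.cell_id, times, vols,
                                           schedule=schedule)
    return curves
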