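"""Synthetic bright-field time-lapse rendering of simulated lineages.

Renders the output of the lineage simulator as image stacks that mimic the
statistical structure of bright-field time-lapse data of coccoid
cyanobacteria — ellipsoidal cells with a dark rim and a slightly bright
interior, a characteristic axis-ratio trajectory over the cell cycle
(≈0.77 at birth shrinking to ≈0.63 at division), perpendicular successive
division planes, post-division sister drift, growth arrest in the dark —
together with pixel-level ground truth (label masks and per-frame cell
tables), so the segmentation/tracking stage can be validated without any
external data.

The optical appearance model (rim depth, blur, noise) is deliberately
simple and fully parameterized; it is a benchmark surface, not a physical
optics model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import json
import math

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .schedule import IlluminationSchedule
from .simulate import ModelSpec, SimCell, simulate_population, cells_to_frame

__all__ = [
    "SceneCell",
    "RenderParams",
    "default_axis_ratio",
    "layout_lineage",
    "render_frame",
    "render_timelapse",
    "generate_timelapse",
]

#: measured axis-ratio trajectory endpoints (birth -> division)
RATIO_BIRTH = 0.77
RATIO_DIVISION = 0.63

#: fraction of the cycle over which the division furrow ramps up
CONSTRICTION_PHASE = 0.8

FRAME_INTERVAL_H = 1.0 / 6.0  # 10-minute imaging interval


def default_axis_ratio(phase: float) -> float:
    """Minor/major axis ratio as a function of normalized cycle phase:
    linear decrease from 0.77 at birth to 0.63 at division."""
    phase = min(max(phase, 0.0), 1.0)
    return RATIO_BIRTH + (RATIO_DIVISION - RATIO_BIRTH) * phase


@dataclass
class SceneCell:
    """One ellipse in a rendered frame, in physical coordinates [µm]."""

    sim_cell_id: int
    center: tuple
    semi_major: float
    semi_minor: float
    orientation: float
    constriction: float = 0.0

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("need semi_major >= semi_minor > 0")

    @property
    def volume(self) -> float:
        """Volume of the prolate ellipsoid the ellipse stands for."""
        return 4.0 / 3.0 * math.pi * self.semi_major * self.semi_minor ** 2


@dataclass(frozen=True)
class RenderParams:
    """Appearance and geometry of the rendered stack.

    ``pixel_size`` defaults to 0.32 µm/px (a plausible 20x-objective
    scale; the true acquisition scale is not fixed by the data model, so
    sweep it when benchmarking).  ``noise_sigma`` is additive Gaussian
    noise as a fraction of the rim contrast.  ``sister_separation`` is the
    extra gap sisters open up over 10-20 min after division.
    """

    pixel_size: float = 0.32
    image_size: int = 256
    psf_sigma: float = 1.0          # px
    noise_sigma: float = 0.05
    rim_contrast: float = 0.35
    interior_contrast: float = 0.08
    background: float = 0.6
    sister_separation: float = 2.0  # µm
    separation_minutes: float = 15.0
    jitter_sigma: float = 0.02      # µm per frame, light
    dark_jitter_factor: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


# --------------------------------------------------------------------------- #
# layout
# --------------------------------------------------------------------------- #

def _semi_axes(volume: float, ratio: float) -> tuple:
    """Invert V = (4/3) π a b², b = ratio · a."""
    a = (3.0 * volume / (4.0 * math.pi * ratio ** 2)) ** (1.0 / 3.0)
    return a, ratio * a


def _boundary_radius(a: float, b: float, alpha: float) -> float:
    """Distance from center to the ellipse boundary in a direction at angle
    ``alpha`` from the major axis."""
    return a * b / math.sqrt((b * math.cos(alpha)) ** 2 +
                             (a * math.sin(alpha)) ** 2)


def _relax_overlaps(scene: list, max_iter: int = 300,
                    gap: float = 1.2) -> None:
    """Push cells apart along center lines until no interiors overlap.

    The clearance also keeps the dark rims of distinct (non-sister) cells
    optically separable; freshly divided sisters start closer and drift
    apart over the first ~15 min."""
    for _ in range(max_iter):
        moved = False
        for i in range(len(scene)):
            for j in range(i + 1, len(scene)):
                ci, cj = scene[i], scene[j]
                dx = cj.center[0] - ci.center[0]
                dy = cj.center[1] - ci.center[1]
                dist = math.hypot(dx, dy)
                if dist < 1e-6:
                    dx, dy, dist = 1e-3, 0.0, 1e-3
                ang = math.atan2(dy, dx)
                ri = _boundary_radius(ci.semi_major, ci.semi_minor,
                                      ang - ci.orientation)
                rj = _boundary_radius(cj.semi_major, cj.semi_minor,
                                      ang - cj.orientation)
                overlap = ri + rj + gap - dist
                if overlap > 1e-6:
                    ux, uy = dx / dist, dy / dist
                    shift = overlap / 2.0
                    ci.center = (ci.center[0] - ux * shift,
                                 ci.center[1] - uy * shift)
                    cj.center = (cj.center[0] + ux * shift,
                                 cj.center[1] + uy * shift)
                    moved = True
        if not moved:
            return
    raise RuntimeError("overlap relaxation did not converge; "
                       "use a larger image_size or fewer founders")


def layout_lineage(
    cells: Sequence[SimCell],
    schedule: Optional[IlluminationSchedule] = None,
    duration: Optional[float] = None,
    frame_interval: float = FRAME_INTERVAL_H,
    axis_ratio_trajectory: Callable[[float], float] = default_axis_ratio,
    params: Optional[RenderParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Place every simulated cell in every frame.

    Returns ``(frame_times, scenes)`` where ``scenes[k]`` is the list of
    :class:`SceneCell` alive at ``frame_times[k]``.  Each ellipse has the
    cell's simulated volume at that time (growth counts only light hours),
    an axis ratio following the cycle-phase trajectory, and an orientation
    perpendicular to its mother's.  Newborn sisters are placed along the
    mother's major axis and drift apart over ~15 min; a pairwise
    relaxation keeps interiors from overlapping.  The division furrow
    (``constriction``) ramps up over the final 20% of the cycle and, like
    growth, freezes during dark intervals.
    """
    params = params or RenderParams()
    rng = rng or np.random.default_rng(params.seed)
    schedule = schedule or IlluminationSchedule.continuous()
    if duration is None:
        duration = max(c.division_time for c in cells)
    n_frames = int(round(duration / frame_interval)) + 1
    frame_times = np.arange(n_frames) * frame_interval

    by_id = {c.id: c for c in cells}
    founders = [c for c in cells if c.parent_id is None]
    field_um = params.image_size * params.pixel_size

    # founder positions: centered grid with margin
    k = math.ceil(math.sqrt(len(founders)))
    pitch = field_um / (k + 1)
    centers: dict = {}
    orientations: dict = {}
    for idx, c in enumerate(founders):
        gx, gy = idx % k, idx // k
        centers[c.id] = ((gx + 1) * pitch, (gy + 1) * pitch)
        orientations[c.id] = float(rng.uniform(0, math.pi))

    sep_frames = max(int(round(params.separation_minutes / 60.0
                               / frame_interval)), 1)
    sep_step = params.sister_separation / 2.0 / sep_frames
    sep_axis: dict = {}       # daughter id -> (ux, uy) outward drift direction
    sep_remaining: dict = {}  # daughter id -> frames of drift left

    scenes = []
    for t in frame_times:
        dark = schedule.state_at(t) == "dark"
        scene = []
        for c in cells:
            if not (c.birth_time - 1e-9 <= t < c.division_time - 1e-9):
                continue
            if c.id not in centers:   # daughter appearing this frame
                _spawn_daughters(c, by_id, centers, orientations,
                                 sep_axis, sep_remaining, sep_frames, rng)
            lt = schedule.light_time(c.birth_time, t)
            vol = c.V_b * math.exp(c.lam * lt)
            phase = min(lt / c.T, 1.0)
            ratio = axis_ratio_trajectory(phase)
            a, b = _semi_axes(vol, ratio)
            constriction = max(0.0, (phase - CONSTRICTION_PHASE)
                               / (1.0 - CONSTRICTION_PHASE))
            # motility jitter: larger in the dark
            jit = params.jitter_sigma * (params.dark_jitter_factor if dark
                                         else 1.0)
            cx, cy = centers[c.id]
            cx += float(rng.normal(0, jit))
            cy += float(rng.normal(0, jit))
            # post-division drift away from the sister
            if sep_remaining.get(c.id, 0) > 0:
                ux, uy = sep_axis[c.id]
                cx += ux * sep_step
                cy += uy * sep_step
                sep_remaining[c.id] -= 1
            centers[c.id] = (cx, cy)
            scene.append(SceneCell(sim_cell_id=c.id, center=(cx, cy),
                                   semi_major=a, semi_minor=b,
                                   orientation=orientations[c.id],
                                   constriction=constriction))
        _relax_overlaps(scene)
        for sc in scene:  # relaxation feeds back into the tracked centers
            centers[sc.sim_cell_id] = sc.center
        scenes.append(scene)
    return frame_times, scenes


def _spawn_daughters(c: SimCell, by_id, centers, orientations,
                     sep_axis, sep_remaining, sep_frames, rng) -> None:
    """Place a newborn pair along the mother's major axis, own axes
    perpendicular to hers."""
    mother = by_id.get(c.parent_id)
    m_center = centers.get(c.parent_id, (0.0, 0.0))
    m_orient = orientations.get(c.parent_id, 0.0)
    a_m, _ = _semi_axes(mother.V_d if mother else 4.0, RATIO_DIVISION)
    ux, uy = math.cos(m_orient), math.sin(m_orient)
    pair = [c.id, c.sister_id] if c.sister_id is not None else [c.id]
    for sign, did in zip((+1, -1), pair):
        if did is None or did in centers:
            continue
        centers[did] = (m_center[0] + sign * ux * a_m / 2.0,
                        m_center[1] + sign * uy * a_m / 2.0)
        orientations[did] = (m_orient + math.pi / 2.0
                             + float(rng.normal(0, 0.03))) % math.pi
        sep_axis[did] = (sign * ux, sign * uy)
        sep_remaining[did] = sep_frames


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #

def render_frame(scene: Sequence[SceneCell], params: RenderParams,
                 rng: Optional[np.random.Generator] = None) -> tuple:
    """Render one frame.

    Returns ``(image, label_mask)``: a float image in roughly [0, 1] with
    dark elliptical rims, slightly bright interiors, Gaussian blur and
    additive noise; and a uint16 mask assigning each pixel the id of the
    nearest covering cell (0 = background).  Cells in late constriction
    get a partial dark furrow across the division plane.
    """
    rng = rng or np.random.default_rng(params.seed)
    n = params.image_size
    img = np.full((n, n), params.background, dtype=float)
    label = np.zeros((n, n), dtype=np.uint16)
    best_d = np.full((n, n), np.inf)

    ps = params.pixel_size
    for cell in scene:
        cx, cy = cell.center
        a, b = cell.semi_major, cell.semi_minor
        reach = (max(a, b) * 1.6) / ps
        x0 = max(int(cx / ps - reach), 0)
        x1 = min(int(cx / ps + reach) + 1, n)
        y0 = max(int(cy / ps - reach), 0)
        y1 = min(int(cy / ps + reach) + 1, n)
        if x0 >= x1 or y0 >= y1:
            raise ValueError("cell outside image bounds")
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx = xx * ps - cx
        dy = yy * ps - cy
        ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
        u = dx * ct + dy * st        # along major axis [µm]
        v = -dx * st + dy * ct
        d = np.sqrt((u / a) ** 2 + (v / b) ** 2)

        rim_w = max(0.5 * ps, 0.12)  # rim half-width [µm-ish in d units]
        rim = np.exp(-((d - 1.0) / (rim_w / min(a, b))) ** 2)
        patch = img[y0:y1, x0:x1]
        patch -= params.rim_contrast * rim
        interior = d < 0.85
        patch[interior] += params.interior_contrast
        if cell.constriction > 0:
            # dark furrow across the division plane (perpendicular to the
            # major axis through the center), deepening with constriction
            furrow = (np.exp(-(u / (0.15 * a)) ** 2) * (d < 1.0)
                      * cell.constriction)
            patch -= 0.6 * params.rim_contrast * furrow

        inside = d <= 1.0
        closer = inside & (d < best_d[y0:y1, x0:x1])
        label[y0:y1, x0:x1][closer] = cell.sim_cell_id + 1
        best_d[y0:y1, x0:x1][closer] = d[closer]

    if params.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, params.psf_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma * params.rim_contrast,
                               size=img.shape)
    return img, label


def render_timelapse(
    cells: Sequence[SimCell],
    schedule: Optional[IlluminationSchedule] = None,
    duration: Optional[float] = None,
    params: Optional[RenderParams] = None,
    frame_interval: float = FRAME_INTERVAL_H,
) -> dict:
    """Lay out and render a whole lineage; pure in-memory variant.

    Returns a dict with ``frame_times``, ``stack`` (float images),
    ``labels`` (uint16 masks), ``scene_table`` (per-frame ground truth)
    and ``lineage_table`` (true per-cycle values).
    """
    params = params or RenderParams()
    rng = np.random.default_rng(params.seed)
    frame_times, scenes = layout_lineage(cells, schedule, duration,
                                         frame_interval, params=params,
                                         rng=rng)
    stack, labels, rows = [], [], []
    for k, (t, scene) in enumerate(zip(frame_times, scenes)):
        img, lab = render_frame(scene, params, rng)
        stack.append(img)
        labels.append(lab)
        for sc in scene:
            rows.append(dict(frame=k, time=t, cell_id=sc.sim_cell_id,
                             x=sc.center[0], y=sc.center[1],
                             semi_major=sc.semi_major,
                             semi_minor=sc.semi_minor,
                             orientation=sc.orientation,
                             volume=sc.volume,
                             constriction=sc.constriction))
    return dict(frame_times=frame_times,
                stack=np.stack(stack),
                labels=np.stack(labels),
                scene_table=pd.DataFrame(rows),
                lineage_table=cells_to_frame(cells))


def _simulate_covering(model: ModelSpec, schedule: IlluminationSchedule,
                       duration: float, n_founders: int,
                       rng_seed: int) -> list:
    """Simulate enough generations that every division inside ``duration``
    has its daughters present."""
    n_gen = 3
    while True:
        rng = np.random.default_rng(rng_seed)
        cells = simulate_population(model, n_founders, n_gen,
                                    schedule=schedule, rng=rng)
        frontier_births = [c.division_time for c in cells
                           if c.generation == n_gen - 1]
        if min(frontier_births) > duration or n_gen > 14:
            return cells
        n_gen += 1


def generate_timelapse(
    model: ModelSpec,
    schedule: Optional[IlluminationSchedule] = None,
    duration: float = 60.0,
    params: Optional[RenderParams] = None,
    out_dir: Optional[str] = None,
    n_founders: int = 1,
    frame_interval: float = FRAME_INTERVAL_H,
) -> dict:
    """End-to-end synthetic dataset: simulate, lay out, render, and
    (optionally) write to disk.

    Writes ``stack.tif`` (image stack), ``labels.tif`` (uint16 label
    stack), ``scene.csv`` and ``lineage.csv`` (ground truth), and
    ``schedule.json`` under ``out_dir`` when given.  Output is
    deterministic for a fixed ``params.seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = params or RenderParams()
    schedule = schedule or IlluminationSchedule.continuous()
    cells = _simulate_covering(model, schedule, duration, n_founders,
                               params.seed)
    result = render_timelapse(cells, schedule, duration, params,
                              frame_interval)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stack_u16 = np.clip(result["stack"] * 20000, 0, 65535).astype(np.uint16)
        try:
            tifffile.imwrite(out / "stack.tif", stack_u16)
            tifffile.imwrite(out / "labels.tif", result["labels"])
            result["scene_table"].to_csv(out / "scene.csv", index=False)
            result["lineage_table"].to_csv(out / "lineage.csv", index=False)
            (out / "schedule.json").write_text(schedule.to_json())
        except OSError as exc:
            raise OSError(f"failed writing synthetic dataset under {out}: "
                          f"{exc}") from exc
        result["paths"] = {p: out / f"{p}" for p in
                           ("stack.tif", "labels.tif", "scene.csv",
                            "lineage.csv", "schedule.json")}
    return result
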