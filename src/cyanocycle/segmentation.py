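"""Single-cell segmentation of bright-field frames.

The reconstruction pipeline mirrors how coccoid cyanobacteria look in
bright field: each cell is a dark elliptical rim around a faintly bright
interior.  A frame is first reduced to a binary foreground mask
(background flattening → robust threshold on the dark rims → hole filling
→ opening → small-object removal).  Connected components ("clusters") are
then described by a small morphology feature vector and scored by a naive
Bayes classifier as a single cell, a doublet (late constriction or
freshly divided, still touching), or a multiplet — no hard geometric
threshold decides cell boundaries; the per-class posteriors travel with
the cluster so the tracking stage can revise them over time.  Clusters
classified as doublets are split by a two-ellipse fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import json
import math

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation as sk_seg

from .geometry import Contour, ellipse_contour

__all__ = [
    "Cluster",
    "MorphologyModel",
    "segment_binary",
    "extract_clusters",
    "classify_cluster",
    "split_cluster",
    "cluster_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("area", "axis_ratio", "solidity", "concavity_count",
                 "two_ellipse_residual_ratio")

CLASS_NAMES = ("singlet", "doublet", "multiplet")

#: minimum believable cell: a 0.8-µm-diameter circle
MIN_CELL_DIAMETER_UM = 0.8


def segment_binary(image: np.ndarray, pixel_size: float,
                   return_offsets: bool = False):
    """Foreground mask of a single bright-field frame.

    The image is background-flattened (difference of a light and a heavy
    Gaussian), the dark cell rims are thresholded at 4 robust standard
    deviations below the background, rims are closed into filled blobs,
    and specks smaller than the minimum cell area are dropped.  A blank
    frame yields an empty mask.

    The detected band straddles the dark rim, whose centerline is the true
    cell boundary, so each component is eroded by half the band thickness —
    as far as its own size allows.  Whatever part of that offset could not
    be eroded (tiny cells at coarse pixel scales) is reported per pixel in
    µm when ``return_offsets`` is set, so that the ellipse-fitting stage
    can subtract it from the fitted semi-axes instead.
    """
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    img = image.astype(float)
    smooth = ndimage.gaussian_filter(img, 1.0)
    bg = ndimage.gaussian_filter(img, 25.0)
    flat = smooth - bg
    mad = np.median(np.abs(flat - np.median(flat)))
    sigma = max(1.4826 * mad, 1e-3 * max(np.ptp(img), 1e-12))
    rim = flat < -4.0 * sigma
    filled = ndimage.binary_fill_holes(rim)
    opened = ndimage.binary_opening(filled, morphology.disk(1))
    filled = ndimage.binary_fill_holes(opened)
    offsets = np.zeros(image.shape, float)
    if filled.any():
        band = rim & filled
        # mean in-band distance is ~1/4 of the band thickness
        half_w = (2.0 * float(ndimage.distance_transform_edt(band)[band].mean())
                  if band.any() else 0.0)
        if half_w > 0.5:
            dist = ndimage.distance_transform_edt(filled)
            lab0, n0 = ndimage.label(filled)
            out = np.zeros_like(filled)
            for i in range(1, n0 + 1):
                comp = lab0 == i
                # never erode a component away: cap by its inradius
                applied = min(half_w, 0.45 * float(dist[comp].max()))
                kept = comp & (dist > applied)
                out |= kept
                offsets[kept] = (half_w - applied) * pixel_size
            filled = out
    min_area_px = math.pi * (MIN_CELL_DIAMETER_UM / 2.0) ** 2 / pixel_size ** 2
    lab, n = ndimage.label(filled)
    if n:
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_area_px)
        filled = np.isin(lab, keep[keep > 0])
    if return_offsets:
        return filled, offsets
    return filled


@dataclass
class Cluster:
    """One connected foreground component and its candidate readings."""

    frame_index: int
    coords: np.ndarray                   # (N, 2) pixel (row, col)
    pixel_size: float
    features: Optional[np.ndarray] = None
    posterior: Optional[dict] = None     # class name -> probability
    centroid: tuple = (0.0, 0.0)         # (x, y) [µm]
    boundary_offset: float = 0.0         # residual rim offset [µm]
    intensity: Optional[np.ndarray] = None  # flattened frame, for refinement
    label_image: Optional[np.ndarray] = None  # per-frame component labels
    label: int = 0                            # own label in label_image
    nearest_label: Optional[np.ndarray] = None  # label of nearest component
    foreground_dist: Optional[np.ndarray] = None  # distance to it [px]

    def __post_init__(self):
        if len(self.coords) == 0:
            raise ValueError("empty cluster")
        r, c = self.coords[:, 0].astype(float), self.coords[:, 1].astype(float)
        self.centroid = (float(c.mean() * self.pixel_size),
                         float(r.mean() * self.pixel_size))


def extract_clusters(mask: np.ndarray, pixel_size: float,
                     frame_index: int = 0,
                     model: Optional["MorphologyModel"] = None,
                     offsets: Optional[np.ndarray] = None,
                     image: Optional[np.ndarray] = None
                     ) -> list[Cluster]:
    """Connected components of a binary mask as :class:`Cluster` objects,
    with features (and posteriors, when a fitted model is given).
    ``offsets`` is the residual boundary-offset image from
    :func:`segment_binary`; passing the original ``image`` as well enables
    sub-pixel contour refinement onto the rim intensity trough."""
    flat = None
    nearest_lab = fg_dist = None
    lab, n = ndimage.label(mask)
    if image is not None:
        img = image.astype(float)
        flat = ndimage.gaussian_filter(img, 1.0) - ndimage.gaussian_filter(
            img, 25.0)
        if n:
            fg_dist, (ir, ic) = ndimage.distance_transform_edt(
                lab == 0, return_indices=True)
            nearest_lab = lab[ir, ic]
    clusters = []
    for i in range(1, n + 1):
        coords = np.argwhere(lab == i)
        off = (float(offsets[coords[:, 0], coords[:, 1]].max())
               if offsets is not None else 0.0)
        cl = Cluster(frame_index=frame_index, coords=coords,
                     pixel_size=pixel_size, boundary_offset=off,
                     intensity=flat, label_image=lab, label=i,
                     nearest_label=nearest_lab, foreground_dist=fg_dist)
        cl.features = cluster_features(cl)
        if model is not None:
            cl.posterior = classify_cluster(cl, model)
        clusters.append(cl)
    return clusters


# --------------------------------------------------------------------------- #
# features
# --------------------------------------------------------------------------- #

def _pixel_moments(coords: np.ndarray):
    """Centroid, principal axes and equivalent-ellipse semi-axes of a pixel
    set (pixel centers as unit-mass points plus the 1/12 pixel term)."""
    pts = coords.astype(float)
    mean = pts.mean(axis=0)
    d = pts - mean
    cov = d.T @ d / len(pts) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    a = 2.0 * math.sqrt(max(evals[1], 1e-12))
    b = 2.0 * math.sqrt(max(evals[0], 1e-12))
    return mean, evecs[:, 1], evecs[:, 0], a, b


def _boundary_coords(coords: np.ndarray) -> np.ndarray:
    rmin, cmin = coords.min(axis=0)
    patch = np.zeros(tuple(coords.max(axis=0) - (rmin, cmin) + 3), bool)
    patch[coords[:, 0] - rmin + 1, coords[:, 1] - cmin + 1] = True
    boundary = patch & ~ndimage.binary_erosion(patch)
    b = np.argwhere(boundary)
    return b + (rmin - 1, cmin - 1)


def _ellipse_residual(coords: np.ndarray, ellipses) -> float:
    """RMS deviation of boundary pixels from the nearest fitted ellipse
    boundary, in normalized elliptical distance."""
    b = _boundary_coords(coords).astype(float)
    dmin = np.full(len(b), np.inf)
    for (cy, cx), u, _, a, bb in ellipses:
        rel = b - (cy, cx)
        s = rel @ u
        t = rel @ np.array([-u[1], u[0]])
        d = np.sqrt((s / a) ** 2 + (t / bb) ** 2)
        dmin = np.minimum(dmin, np.abs(d - 1.0))
    return float(np.sqrt(np.mean(dmin ** 2)))


def _two_ellipse_fit(coords: np.ndarray, n_iter: int = 8):
    """EM-style two-ellipse decomposition of a pixel set: initialize by
    bisecting along the principal axis, then alternate assignment to the
    nearer ellipse and per-group moment refits."""
    mean, u, v, a, b = _pixel_moments(coords)
    proj = (coords - mean) @ u
    groups = proj >= np.median(proj)
    for _ in range(n_iter):
        parts = []
        for g in (groups, ~groups):
            if g.sum() < 4:
                return None
            parts.append(_pixel_moments(coords[g]))
        d = []
        for (m, uu, vv, aa, bb) in parts:
            rel = coords - m
            s = rel @ uu
            t = rel @ np.array([-uu[1], uu[0]])
            d.append(np.sqrt((s / aa) ** 2 + (t / bb) ** 2))
        new_groups = d[0] <= d[1]
        if (new_groups == groups).all():
            break
        groups = new_groups
    return parts, groups


def cluster_features(cluster: Cluster) -> np.ndarray:
    """Morphology feature vector used by the classifier: physical area,
    equivalent-ellipse axis ratio, solidity, count of significant boundary
    concavities, and the two-ellipse/one-ellipse fit residual ratio
    (well below 1 for genuine doublets)."""
    coords = cluster.coords
    ps = cluster.pixel_size
    area = len(coords) * ps ** 2

    mean, u, v, a, b = _pixel_moments(coords)
    axis_ratio = b / a

    # solidity and concavities from the convex hull
    rmin, cmin = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - (rmin, cmin) + 1)
    patch = np.zeros(shape, bool)
    patch[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    hull = morphology.convex_hull_image(patch)
    solidity = patch.sum() / max(hull.sum(), 1)
    defects = hull & ~patch
    dlab, nd = ndimage.label(defects)
    sizes = np.bincount(dlab.ravel())[1:] if nd else np.array([])
    n_conc = int((sizes >= 4).sum())

    one = _ellipse_residual(coords, [(mean, u, v, a, b)])
    two_fit = _two_ellipse_fit(coords)
    if two_fit is None:
        ratio = 1.0
    else:
        two = _ellipse_residual(coords, two_fit[0])
        ratio = two / max(one, 1e-6)
    return np.array([area, axis_ratio, solidity, float(n_conc), ratio])


# --------------------------------------------------------------------------- #
# classifier
# --------------------------------------------------------------------------- #

@dataclass
class MorphologyModel:
    """Gaussian naive Bayes over the morphology features, fitted on
    labeled clusters (synthetic renders with known cell counts stand in
    for hand-annotated morphologies)."""

    means: Optional[np.ndarray] = None       # (3, n_features)
    stds: Optional[np.ndarray] = None
    priors: Optional[np.ndarray] = None
    fitted: bool = False

    def fit(self, features: np.ndarray, labels: Sequence[int]
            ) -> "MorphologyModel":
        """``labels``: 1 (singlet), 2 (doublet), 3+ (multiplet)."""
        X = np.asarray(features, float)
        y = np.clip(np.asarray(labels, int), 1, 3) - 1
        means, stds, priors = [], [], []
        for k in range(3):
            sel = X[y == k]
            if len(sel) < 2:
                raise ValueError(f"need >= 2 examples of class "
                                 f"{CLASS_NAMES[k]!r}")
            means.append(sel.mean(axis=0))
            stds.append(np.maximum(sel.std(axis=0), 0.05 * np.abs(
                sel.mean(axis=0)) + 1e-3))
            priors.append(len(sel))
        self.means = np.array(means)
        self.stds = np.array(stds)
        self.priors = np.array(priors, float) / len(X)
        self.fitted = True
        return self

    def log_likelihood(self, x: np.ndarray) -> np.ndarray:
        z = (x[None, :] - self.means) / self.stds
        return (-0.5 * z ** 2 - np.log(self.stds)).sum(axis=1) + np.log(
            self.priors)

    def to_json(self) -> str:
        return json.dumps(dict(means=self.means.tolist(),
                               stds=self.stds.tolist(),
                               priors=self.priors.tolist()))

    @classmethod
    def from_json(cls, s: str) -> "MorphologyModel":
        d = json.loads(s)
        return cls(means=np.array(d["means"]), stds=np.array(d["stds"]),
                   priors=np.array(d["priors"]), fitted=True)


def classify_cluster(cluster: Cluster, model: MorphologyModel) -> dict:
    """Posterior over {singlet, doublet, multiplet} for one cluster."""
    if not model.fitted:
        raise ValueError("MorphologyModel is not fitted")
    x = cluster.features if cluster.features is not None else \
        cluster_features(cluster)
    ll = model.log_likelihood(np.asarray(x, float))
    ll -= ll.max()
    p = np.exp(ll)
    p /= p.sum()
    return dict(zip(CLASS_NAMES, p.tolist()))


# --------------------------------------------------------------------------- #
# splitting
# --------------------------------------------------------------------------- #

def split_cluster(cluster: Cluster, k: int) -> tuple:
    """Decompose a cluster into ``k`` smooth elliptical contours [µm].

    For k=2 the two-ellipse fit is initialized from the principal-axis
    bisection; if it degenerates, a watershed split seeded at the two
    distance-transform maxima is used instead and the result is flagged
    low-confidence.  Returns ``(contours, residual, low_confidence)``.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    coords = cluster.coords
    ps = cluster.pixel_size
    off_px = cluster.boundary_offset / ps
    if k == 1:
        mean, u, v, a, b = _pixel_moments(coords)
        resid = _ellipse_residual(coords, [(mean, u, v, a, b)])
        off = min(off_px, 0.35 * b)  # unresolvably small cells: partial only
        a, b = a - off, b - off
        sc = _refine_scale(cluster, mean, u, a, b)
        return [_ellipse_to_contour(mean, u, sc * a, sc * b, ps,
                                    cluster.frame_index)], resid, False

    fit = _two_ellipse_fit(coords)
    if fit is not None:
        parts, groups = fit
        resid = _ellipse_residual(coords, parts)
        contours = []
        adj = []
        for (m, uu, vv, aa, bb) in parts:
            off = min(off_px, 0.35 * bb)
            adj.append((m, uu, aa - off, bb - off))
        for i, (m, uu, aa, bb) in enumerate(adj):
            others = [adj[j] for j in range(len(adj)) if j != i]
            sc = _refine_scale(cluster, m, uu, aa, bb, exclude=others)
            contours.append(_ellipse_to_contour(m, uu, sc * aa, sc * bb, ps,
                                                cluster.frame_index))
        return contours, resid, False

    # watershed fallback
    rmin, cmin = coords.min(axis=0)
    shape = tuple(coords.max(axis=0) - (rmin, cmin) + 1)
    patch = np.zeros(shape, bool)
    patch[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    dist = ndimage.distance_transform_edt(patch)
    flat = dist.ravel()
    seeds = np.zeros_like(patch, dtype=int)
    order = np.argsort(flat)[::-1]
    first = np.unravel_index(order[0], shape)
    seeds[first] = 1
    far = None
    for idx in order[1:]:
        rc = np.unravel_index(idx, shape)
        if (rc[0] - first[0]) ** 2 + (rc[1] - first[1]) ** 2 > dist[first] ** 2:
            far = rc
            break
    seeds[far if far is not None else first] = 2
    ws = sk_seg.watershed(-dist, seeds, mask=patch)
    contours = []
    for lab in (1, 2):
        sub = np.argwhere(ws == lab) + (rmin, cmin)
        if len(sub) < 4:
            sub = coords
        mean, uu, vv, aa, bb = _pixel_moments(sub)
        off = min(off_px, 0.35 * bb)
        contours.append(_ellipse_to_contour(mean, uu, aa - off, bb - off,
                                            ps, cluster.frame_index))
    resid = _ellipse_residual(coords, [_pixel_moments(np.argwhere(
        ws == lab) + (rmin, cmin)) for lab in (1, 2)])
    return contours, resid, True


def _refine_scale(cluster: Cluster, mean_rc, u_rc, a_px, b_px,
                  exclude=()) -> float:
    """Scale factor that centers the fitted ellipse on the dark rim
    trough of the flattened image (parabolic sub-step refinement).
    ``exclude`` lists other fitted ellipses (same component) whose
    neighbourhood must not attract the fit."""
    flat = cluster.intensity
    if flat is None or b_px < 1.5:
        return 1.0
    t = np.linspace(0.0, 2.0 * math.pi, 48, endpoint=False)
    ex = a_px * np.cos(t)
    ey = b_px * np.sin(t)
    uy, ux = u_rc  # (row, col) components of the major axis
    rows = mean_rc[0] + uy * ex - ux * ey
    cols = mean_rc[1] + ux * ex + uy * ey
    d_rows = rows - mean_rc[0]
    d_cols = cols - mean_rc[1]
    scales = np.linspace(0.75, 1.30, 23)
    means = np.empty(len(scales))
    for i, sc in enumerate(scales):
        rr = mean_rc[0] + sc * d_rows
        cc = mean_rc[1] + sc * d_cols
        vals = ndimage.map_coordinates(flat, [rr, cc], order=1,
                                       mode="nearest")
        keep = np.ones(len(vals), bool)
        if cluster.nearest_label is not None:
            # ignore sample points in or near a *different* component
            # (a close sister's rim would otherwise drag the fit outward)
            labs = ndimage.map_coordinates(cluster.nearest_label, [rr, cc],
                                           order=0, mode="nearest")
            d_fg = ndimage.map_coordinates(cluster.foreground_dist, [rr, cc],
                                           order=1, mode="nearest")
            keep &= (labs == cluster.label) | (d_fg > 2.5)
        elif cluster.label_image is not None:
            labs = ndimage.map_coordinates(cluster.label_image, [rr, cc],
                                           order=0, mode="nearest")
            keep &= (labs == 0) | (labs == cluster.label)
        for (m2, u2, a2, b2) in exclude:
            rel_r = rr - m2[0]
            rel_c = cc - m2[1]
            s2 = rel_r * u2[0] + rel_c * u2[1]
            t2 = -rel_r * u2[1] + rel_c * u2[0]
            d2 = np.sqrt((s2 / a2) ** 2 + (t2 / b2) ** 2)
            keep &= d2 > 1.15
        if keep.sum() < len(vals) // 2:
            return 1.0
        vals = vals[keep]
        means[i] = float(vals.mean())
    j = int(np.argmin(means))
    if 0 < j < len(scales) - 1:
        y0, y1, y2 = means[j - 1], means[j], means[j + 1]
        denom = (y0 - 2 * y1 + y2)
        frac = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        return float(scales[j] + frac * (scales[1] - scales[0]))
    return float(scales[j])


def _ellipse_to_contour(mean_rc, u_rc, a_px, b_px, pixel_size,
                        frame_index) -> Contour:
    """Fitted pixel-space ellipse -> physical-space boundary contour.
    Pixel moments use (row, col); contours live in (x, y) µm."""
    b_px = max(b_px, 0.8)
    a_px = max(a_px, b_px)
    cy, cx = mean_rc
    orientation = math.atan2(u_rc[0], u_rc[1])  # row component -> y
    return ellipse_contour(center=(cx * pixel_size, cy * pixel_size),
                           semi_major=a_px * pixel_size,
                           semi_minor=b_px * pixel_size,
                           orientation=orientation,
                           frame_index=frame_index)
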