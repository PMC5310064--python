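"""Training fixtures for the morphology classifier.

The cluster classifier needs labeled examples of singlets, doublets and
multiplets.  Real pipelines train on hand-annotated morphologies; here the
renderer supplies synthetic examples with known composition: lone
ellipses across the realistic size/eccentricity range (including late
constriction, which still belongs to the *singlet* class — a constricting
mother is one cell until it actually divides), freshly divided touching
sister pairs, and small clumps.
"""

from __future__ import annotations

from typing import Optional

import math

import numpy as np

from .imaging import RenderParams, SceneCell, render_frame
from .segmentation import (MorphologyModel, cluster_features,
                           extract_clusters, segment_binary)

__all__ = ["train_morphology_model", "synthetic_training_set"]


def _features_of_scene(scene, params, rng):
    img, _ = render_frame(scene, params, rng)
    mask = segment_binary(img, params.pixel_size)
    clusters = extract_clusters(mask, params.pixel_size)
    if not clusters:
        return None
    biggest = max(clusters, key=lambda c: len(c.coords))
    return biggest.features


def synthetic_training_set(params: Optional[RenderParams] = None,
                           n_per_class: int = 30,
                           seed: int = 7) -> tuple:
    """Rendered feature vectors with composition labels (1, 2, 3)."""
    params = params or RenderParams(image_size=96, noise_sigma=0.02)
    rng = np.random.default_rng(seed)
    mid = params.image_size * params.pixel_size / 2.0
    X, y = [], []

    for _ in range(n_per_class):
        a = rng.uniform(0.8, 1.6)
        ratio = rng.uniform(0.60, 0.85)
        theta = rng.uniform(0, math.pi)
        constr = rng.uniform(0, 1) if rng.uniform() < 0.4 else 0.0
        scene = [SceneCell(0, (mid, mid), a, ratio * a, theta,
                           constriction=constr)]
        f = _features_of_scene(scene, params, rng)
        if f is not None:
            X.append(f)
            y.append(1)

    for _ in range(n_per_class):
        # freshly divided, touching sisters: separation along the former
        # mother axis, own major axes perpendicular to it
        a = rng.uniform(0.7, 1.2)
        ratio = rng.uniform(0.70, 0.85)
        theta = rng.uniform(0, math.pi)
        sep_axis = theta + math.pi / 2.0
        gap = ratio * a * 2 * rng.uniform(0.95, 1.1)
        dx, dy = math.cos(sep_axis) * gap / 2, math.sin(sep_axis) * gap / 2
        scene = [SceneCell(0, (mid - dx, mid - dy), a, ratio * a, theta),
                 SceneCell(1, (mid + dx, mid + dy), a, ratio * a,
                           theta + rng.normal(0, 0.1))]
        f = _features_of_scene(scene, params, rng)
        if f is not None:
            X.append(f)
            y.append(2)

    for _ in range(n_per_class):
        n_cells = int(rng.integers(3, 6))
        a = rng.uniform(0.7, 1.1)
        scene = []
        for k in range(n_cells):
            ang = 2 * math.pi * k / n_cells + rng.normal(0, 0.2)
            r = a * 1.2
            scene.append(SceneCell(k, (mid + r * math.cos(ang),
                                       mid + r * math.sin(ang)),
                                   a, 0.75 * a, rng.uniform(0, math.pi)))
        f = _features_of_scene(scene, params, rng)
        if f is not None:
            X.append(f)
            y.append(3)

    return np.array(X), np.array(y)


def train_morphology_model(params: Optional[RenderParams] = None,
                           n_per_class: int = 30,
                           seed: int = 7) -> MorphologyModel:
    """Fit the naive Bayes morphology model on synthetic renders."""
    X, y = synthetic_training_set(params, n_per_class, seed)
    return MorphologyModel().fit(X, y)
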