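"""Stochastic single-cell growth/division simulator for coccoid bacteria.

Implements the three canonical cell-size-control rules:

* **sizer** — divide when the cell reaches a target volume ``V_s``;
* **timer** — divide after a target duration ``T*`` of growth (light-time);
* **adder** — divide after adding a target volume increment ``Δ`` since
  birth.

Cells grow exponentially in volume, ``V(t) = V_b * exp(λ * t_light)``,
where ``t_light`` counts only hours spent under illumination: growth and
division arrest completely in the dark, which is the behaviour observed
for *Synechocystis* under light-dark cycles.  Each rule's trigger carries
multiplicative Gaussian noise; divisions are near-symmetric with Gaussian
asymmetry; each daughter draws an independent growth rate.

Under these rules, in a steady-state population, the least-squares slope
of division volume against birth volume is 0 (sizer), +1 (adder) and +2
(timer, when the mean per-cycle volume fold change is 2); those analytic
slopes are what discriminates the rules from single-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import math
import numpy as np
import pandas as pd

from .schedule import IlluminationSchedule

__all__ = [
    "ModelSpec",
    "SimCell",
    "simulate_population",
    "ideal_model_slope",
    "simulated_slope_distribution",
    "replicate_slopes",
    "calibrate_noise",
    "CalibrationError",
    "cells_to_frame",
    "steady_state_birth_volume",
    "SLOPE_STATISTICS",
]

RULES = ("sizer", "timer", "adder")

#: regression statistics computable from one replicate of simulated cycles
SLOPE_STATISTICS = ("Vd_vs_Vb", "dV_vs_Vb", "T_vs_Vb", "dT_vs_dVb_sisters")

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class ModelSpec:
    """Parameterization of one size-control model.

    ``trigger_mean`` is the rule's target quantity: division volume for the
    sizer [volume units], light-time duration for the timer [h], added
    volume for the adder [volume units].  ``trigger_cv`` is the CV of the
    per-cycle multiplicative trigger noise.  ``asym_sd`` is the SD of the
    division asymmetry ``a`` (daughters receive fractions (1±a)/2 of the
    mother's division volume).  Growth rates λ are drawn per cell from
    Normal(mean, cv*mean), truncated below at 0.1*mean.
    ``size_drift_rate`` optionally scales the trigger linearly with the
    cell's wall-clock birth time (fraction per hour, default 0), emulating
    a slow drift of mean cell size over an experiment.
    """

    rule: str
    trigger_mean: float
    trigger_cv: float = 0.0
    asym_sd: float = 0.0
    growth_rate_mean: float = 0.055
    growth_rate_cv: float = 0.0
    size_drift_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.trigger_mean <= 0:
            raise ValueError("trigger_mean must be positive")
        if not (0 <= self.asym_sd < 0.5):
            raise ValueError("asym_sd must lie in [0, 0.5)")
        if self.growth_rate_mean <= 0:
            raise ValueError("growth_rate_mean must be positive")
        if self.trigger_cv < 0 or self.growth_rate_cv < 0:
            raise ValueError("CVs must be non-negative")


@dataclass
class SimCell:
    """One completed cell cycle in a simulated lineage.

    Times are hours.  ``T`` is the generation time in *light-time*;
    ``birth_time`` and ``division_time`` are wall-clock and account for
    any intervening dark gaps.
    """

    id: int
    parent_id: Optional[int]
    sister_id: Optional[int]
    generation: int
    birth_time: float
    V_b: float
    lam: float
    T: float
    V_d: float
    division_time: float


def steady_state_birth_volume(spec: ModelSpec) -> float:
    """Mean birth volume at the model's steady state (1.0 for the timer,
    which sets no size scale of its own)."""
    if spec.rule == "adder":
        return spec.trigger_mean
    if spec.rule == "sizer":
        return spec.trigger_mean / 2.0
    return 1.0


def _draw_lambda(rng: np.random.Generator, spec: ModelSpec, n: int) -> np.ndarray:
    mean, cv = spec.growth_rate_mean, spec.growth_rate_cv
    lam = rng.normal(mean, cv * mean, size=n)
    floor = 0.1 * mean
    for _ in range(_MAX_REDRAWS):
        bad = lam < floor
        if not bad.any():
            return lam
        lam[bad] = rng.normal(mean, cv * mean, size=int(bad.sum()))
    return np.maximum(lam, floor)


def _draw_trigger(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative trigger factors (1 + η), redrawn until positive."""
    f = 1.0 + rng.normal(0.0, cv, size=n)
    for _ in range(_MAX_REDRAWS):
        bad = f <= 0
        if not bad.any():
            return f
        f[bad] = 1.0 + rng.normal(0.0, cv, size=int(bad.sum()))
    raise RuntimeError("trigger noise redraw limit exceeded "
                       f"(trigger_cv={cv} leaves no positive mass)")


def simulate_population(
    model: ModelSpec,
    n_founders: int,
    n_generations: int,
    schedule: Optional[IlluminationSchedule] = None,
    founder_volumes: Optional[Sequence[float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[SimCell]:
    """Simulate complete cell cycles for ``n_generations`` generations.

    Founders form generation 0; every cell in generations
    ``0 .. n_generations-1`` completes its cycle and appears in the output
    (``n_founders * (2**n_generations - 1)`` cells in total).  Unless
    given, founder volumes are lognormal with mean equal to the model's
    steady-state birth volume and CV 0.12, the birth-size spread measured
    for *Synechocystis* under continuous light.

    Growth is gated by ``schedule``: volume is constant in the dark and
    the timer accumulates only light-time.  A division whose light budget
    is exhausted exactly at a dark onset is stamped at that boundary, so
    no division falls strictly inside a dark interval.
    """
    if n_founders < 1 or n_generations < 1:
        raise ValueError("n_founders and n_generations must be >= 1")
    if schedule is None:
        schedule = IlluminationSchedule.continuous()
    if rng is None:
        rng = np.random.default_rng(model.seed)

    if founder_volumes is not None:
        vb = np.asarray(founder_volumes, dtype=float)
        if len(vb) != n_founders:
            raise ValueError("founder_volumes length must equal n_founders")
        if (vb <= 0).any():
            raise ValueError("founder volumes must be positive")
    else:
        mean_vb = steady_state_birth_volume(model)
        cv = 0.12
        sigma = math.sqrt(math.log(1 + cv ** 2))
        mu = math.log(mean_vb) - sigma ** 2 / 2
        vb = rng.lognormal(mu, sigma, size=n_founders)

    lam = _draw_lambda(rng, model, n_founders)

    cells: list[SimCell] = []
    next_id = 0
    # generation-synchronous frontier: (id, parent, sister, gen, birth wall time, V_b, lam)
    frontier = [(i, None, None, 0, 0.0, vb[i], lam[i]) for i in range(n_founders)]
    next_id = n_founders

    for gen in range(n_generations):
        n = len(frontier)
        vb_g = np.array([c[5] for c in frontier])
        lam_g = np.array([c[6] for c in frontier])
        tb_g = np.array([c[4] for c in frontier])

        drift = 1.0 + model.size_drift_rate * tb_g if model.size_drift_rate else 1.0
        trig = model.trigger_mean * drift * _draw_trigger(rng, model.trigger_cv, n)

        if model.rule == "sizer":
            # a sizer target below the current volume has no meaning; redraw
            for _ in range(_MAX_REDRAWS):
                bad = trig <= vb_g
                if not bad.any():
                    break
                trig[bad] = (model.trigger_mean
                             * (drift[bad] if np.ndim(drift) else drift)
                             * _draw_trigger(rng, model.trigger_cv, int(bad.sum())))
            else:
                raise RuntimeError("sizer target persistently below birth volume")
            vd_g = trig
            T_g = np.log(vd_g / vb_g) / lam_g
        elif model.rule == "adder":
            vd_g = vb_g + trig
            T_g = np.log(vd_g / vb_g) / lam_g
        else:  # timer
            T_g = trig
            vd_g = vb_g * np.exp(lam_g * T_g)

        a_g = rng.normal(0.0, model.asym_sd, size=n)
        a_g = np.clip(a_g, -0.999, 0.999)
        lam_d = _draw_lambda(rng, model, 2 * n)

        new_frontier = []
        for i, (cid, pid, sid, g, tb, vb_i, lam_i) in enumerate(frontier):
            t_div = schedule.advance_light(tb, float(T_g[i]))
            cells.append(SimCell(id=cid, parent_id=pid, sister_id=sid,
                                 generation=g, birth_time=tb, V_b=float(vb_i),
                                 lam=float(lam_i), T=float(T_g[i]),
                                 V_d=float(vd_g[i]), division_time=t_div))
            if gen < n_generations - 1:
                d1, d2 = next_id, next_id + 1
                next_id += 2
                f1 = (1.0 + a_g[i]) / 2.0
                new_frontier.append((d1, cid, d2, g + 1, t_div,
                                     float(vd_g[i] * f1), float(lam_d[2 * i])))
                new_frontier.append((d2, cid, d1, g + 1, t_div,
                                     float(vd_g[i] * (1.0 - f1)), float(lam_d[2 * i + 1])))
        frontier = new_frontier

    return cells


def cells_to_frame(cells: Iterable[SimCell]) -> pd.DataFrame:
    """One row per completed cycle; the simulator's CSV schema."""
    return pd.DataFrame(
        [
            dict(id=c.id, parent_id=c.parent_id, sister_id=c.sister_id,
                 generation=c.generation, birth_time=c.birth_time, V_b=c.V_b,
                 lam=c.lam, T=c.T, V_d=c.V_d, division_time=c.division_time)
            for c in cells
        ]
    )


def ideal_model_slope(rule: str) -> float:
    """Analytic division-volume-vs-birth-volume slope under ideal
    conditions: 0 (sizer), +1 (adder), +2 (timer at steady state, where
    the mean per-cycle volume fold change is 2)."""
    slopes = {"sizer": 0.0, "adder": 1.0, "timer": 2.0}
    try:
        return slopes[rule]
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}") from None


# --------------------------------------------------------------------------- #
# replicate-level slope statistics
# --------------------------------------------------------------------------- #

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("zero variance in x")
    return float(xc @ (y - y.mean())) / denom


def _replicate_statistic(cells: list[SimCell], statistic: str,
                         n_cells: int, rng: np.random.Generator,
                         burn_in: int) -> float:
    post = [c for c in cells if c.generation >= burn_in]
    if statistic == "dT_vs_dVb_sisters":
        by_id = {c.id: c for c in post}
        xs, ys = [], []
        seen = set()
        for c in post:
            if c.sister_id is None or c.sister_id not in by_id or c.id in seen:
                continue
            s = by_id[c.sister_id]
            seen.update((c.id, s.id))
            dv = (c.V_b - s.V_b) / (c.V_b + s.V_b)
            dt = (c.T - s.T) / (c.T + s.T)
            xs.extend((dv, -dv))
            ys.extend((dt, -dt))
        n_pairs = min(len(xs) // 2, max(n_cells // 2, 3))
        idx = rng.choice(len(xs) // 2, size=n_pairs, replace=False)
        x = np.array([[xs[2 * i], xs[2 * i + 1]] for i in idx]).ravel()
        y = np.array([[ys[2 * i], ys[2 * i + 1]] for i in idx]).ravel()
        return _ols_slope(x, y)

    idx = rng.choice(len(post), size=min(n_cells, len(post)), replace=False)
    sub = [post[i] for i in idx]
    vb = np.array([c.V_b for c in sub])
    vd = np.array([c.V_d for c in sub])
    T = np.array([c.T for c in sub])
    vbn = vb / vb.mean()
    if statistic == "Vd_vs_Vb":
        return _ols_slope(vbn, vd / vb.mean())
    if statistic == "dV_vs_Vb":
        return _ols_slope(vbn, (vd - vb) / vb.mean())
    if statistic == "T_vs_Vb":
        return _ols_slope(vbn, T / T.mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def _generations_for(n_cells: int, burn_in: int) -> tuple[int, int]:
    """(n_founders, n_generations) giving comfortably more than ``n_cells``
    post-burn-in cycles with three extra post-burn-in generations."""
    n_gen = burn_in + 3
    per_founder = sum(2 ** g for g in range(burn_in, n_gen))
    n_founders = max(2, math.ceil(1.3 * n_cells / per_founder))
    return n_founders, n_gen


def replicate_slopes(
    model: ModelSpec,
    statistics: Sequence[str],
    n_replicates: int,
    cells_per_replicate: int,
    schedule: Optional[IlluminationSchedule] = None,
    burn_in: int = 3,
) -> dict[str, np.ndarray]:
    """Per-replicate least-squares slopes for each requested statistic.

    Each replicate simulates an independent population (its own seeded
    stream derived from ``model.seed``), discards ``burn_in`` generations,
    subsamples ``cells_per_replicate`` cycles (or the matching number of
    complete sister pairs) and regresses the normalized quantities:
    volumes are normalized by the replicate's mean birth volume and
    generation times by the mean generation time.
    """
    if cells_per_replicate < 30:
        raise ValueError("cells_per_replicate must be >= 30")
    for s in statistics:
        if s not in SLOPE_STATISTICS:
            raise ValueError(f"unknown statistic {s!r}")
    n_founders, n_gen = _generations_for(cells_per_replicate, burn_in)
    out = {s: np.empty(n_replicates) for s in statistics}
    ss = np.random.SeedSequence([int(model.seed) & 0x7FFFFFFF, 0x5e0])
    for r, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        cells = simulate_population(model, n_founders, n_gen,
                                    schedule=schedule, rng=rng)
        for s in statistics:
            out[s][r] = _replicate_statistic(cells, s, cells_per_replicate,
                                             rng, burn_in)
    return out


def simulated_slope_distribution(
    model: ModelSpec,
    statistic: str,
    n_replicates: int,
    cells_per_replicate: int,
    schedule: Optional[IlluminationSchedule] = None,
    burn_in: int = 3,
) -> tuple[float, float]:
    """Mean and SD of the normalized regression slope across replicate
    simulations (see :func:`replicate_slopes`)."""
    slopes = replicate_slopes(model, [statistic], n_replicates,
                              cells_per_replicate, schedule, burn_in)[statistic]
    return float(slopes.mean()), float(slopes.std(ddof=1))


# --------------------------------------------------------------------------- #
# noise calibration
# --------------------------------------------------------------------------- #

class CalibrationError(ValueError):
    """Target birth-volume CV unreachable; ``floor`` is the CV obtained
    with zero trigger noise."""

    def __init__(self, msg: str, floor: float):
        super().__init__(msg)
        self.floor = floor


def _birth_cv(spec: ModelSpec, n_cells: int = 4000, burn_in: int = 3,
              seed: int = 12345) -> float:
    n_founders, n_gen = _generations_for(n_cells, burn_in)
    rng = np.random.default_rng(seed)
    cells = simulate_population(spec, n_founders, n_gen, rng=rng)
    vb = np.array([c.V_b for c in cells if c.generation >= burn_in])
    return float(vb.std() / vb.mean())


def calibrate_noise(
    rule: str,
    target_birth_cv: float,
    growth_rate_cv: float,
    asym_sd: float,
    growth_rate_mean: float = 0.055,
    tol: float = 0.01,
    seed: int = 0,
    on_unreachable: str = "error",
) -> ModelSpec:
    """Find the trigger CV reproducing a target steady-state birth-volume CV.

    Bisection on ``trigger_cv`` with a fixed internal seed schedule so the
    result is deterministic.  The other noise sources (growth-rate CV and
    division asymmetry) are held at the supplied values; the returned spec
    carries the caller's ``seed``.

    If the target lies below the CV floor induced by the other noise
    sources alone, raises :class:`CalibrationError` naming the floor —
    or, with ``on_unreachable="floor"``, returns the zero-trigger-noise
    spec (useful for the timer, which has no size homeostasis and whose
    birth-size spread therefore cannot be dialled down to a small target).
    """
    if not (0 < target_birth_cv < 0.5):
        if target_birth_cv == 0 and growth_rate_cv == 0 and asym_sd == 0:
            return ModelSpec(rule=rule, trigger_mean=_default_trigger(rule, growth_rate_mean),
                             trigger_cv=0.0, asym_sd=0.0,
                             growth_rate_mean=growth_rate_mean,
                             growth_rate_cv=0.0, seed=seed)
        raise ValueError("target_birth_cv must lie in (0, 0.5)")

    def spec_for(tcv: float) -> ModelSpec:
        return ModelSpec(rule=rule, trigger_mean=_default_trigger(rule, growth_rate_mean),
                         trigger_cv=tcv, asym_sd=asym_sd,
                         growth_rate_mean=growth_rate_mean,
                         growth_rate_cv=growth_rate_cv, seed=seed)

    floor = _birth_cv(spec_for(0.0))
    if floor > target_birth_cv + tol:
        if on_unreachable == "floor":
            return spec_for(0.0)
        raise CalibrationError(
            f"target birth CV {target_birth_cv:.3f} unreachable for {rule}: "
            f"other noise sources alone give CV {floor:.3f}", floor)

    lo, hi = 0.0, 0.6
    cv_hi = _birth_cv(spec_for(hi))
    if cv_hi < target_birth_cv:
        raise CalibrationError(
            f"target birth CV {target_birth_cv:.3f} above reachable range "
            f"(CV {cv_hi:.3f} at trigger_cv={hi})", cv_hi)
    for _ in range(40):
        mid = (lo + hi) / 2
        cv = _birth_cv(spec_for(mid))
        if abs(cv - target_birth_cv) <= tol / 2:
            return spec_for(mid)
        if cv < target_birth_cv:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    mid = (lo + hi) / 2
    final = spec_for(mid)
    if abs(_birth_cv(final) - target_birth_cv) > tol:
        raise CalibrationError("bisection failed to converge", floor)
    return final


def _default_trigger(rule: str, growth_rate_mean: float) -> float:
    """Natural trigger scale: unit added volume (adder), twice the unit
    birth volume (sizer), one mean doubling time (timer)."""
    if rule == "adder":
        return 1.0
    if rule == "sizer":
        return 2.0
    if rule == "timer":
        return math.log(2.0) / growth_rate_mean
    raise ValueError(f"unknown rule {rule!r}")
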