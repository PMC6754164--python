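"""Genetic-algorithm estimation of the signaling-cascade rate constants.

The cascade parameters are fitted to normalised protein time courses
(pERK, Skp2, pAKT, AR in [0, 1]) measured under single-ligand stimulation
(WNT5A only, or EGF only) at t in {0, 30, 60, 420} minutes; Skp2 enters
only at 30 and 60 minutes because its level is indistinguishable from
control afterwards.  The objective is the plain L1 misfit

    J(theta) = sum_{i, t} | X_it - Xhat_it(theta) |

minimised by a real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation, one elite).  Western-blot observations are
not shipped with the package; :func:`generate_synthetic_observations`
produces surrogate observation tables from a known parameter set plus
Gaussian noise, which is also how the parameter-recovery tests work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .signaling import (
    IntegrationError,
    LigandInput,
    ODEParams,
    PARAM_NAMES,
    SignalingState,
    integrate,
)

__all__ = [
    "Observation",
    "ObservationSet",
    "GAConfig",
    "objective",
    "fit_ga",
    "generate_synthetic_observations",
    "DEFAULT_BOUNDS",
]

PROTEINS = ("erk", "skp2", "akt", "ar")
_PROTEIN_COL = {"erk": 0, "skp2": 1, "akt": 2, "ar": 3}
OBSERVATION_TIMES = (0.0, 30.0, 60.0, 420.0)
SKP2_TIMES = (30.0, 60.0)
CONDITIONS = ("wnt5a", "egf")

#: default per-parameter search bounds for normalised (dimensionless) data
DEFAULT_BOUNDS = {
    name: ((1e-4, 1.0) if name[0] in "kd" else (1e-3, 10.0)) for name in PARAM_NAMES
}


@dataclass(frozen=True)
class Observation:
    protein: str  # one of PROTEINS
    t_min: float
    condition: str  # "wnt5a" or "egf" (single-ligand stimulation)
    dose: float  # ligand dose in [0, 1]
    value: float  # measured activity, >= 0

    def __post_init__(self):
        if self.protein not in PROTEINS:
            raise ValueError(f"unknown protein {self.protein!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.t_min not in OBSERVATION_TIMES:
            raise ValueError(f"time {self.t_min} outside the design {OBSERVATION_TIMES}")
        if self.protein == "skp2" and self.t_min not in SKP2_TIMES:
            raise ValueError("Skp2 is observed only at 30 and 60 minutes")
        if self.value < 0:
            raise ValueError("observed value must be >= 0")


class ObservationSet:
    """An ordered collection of protein observations.

    Round-trips to CSV with columns ``protein,t_min,condition,dose,value``.
    """

    def __init__(self, entries: Sequence[Observation]):
        self.entries = list(entries)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (o.protein, o.t_min, o.condition, o.dose, o.value)
                for o in self.entries
            ],
            columns=["protein", "t_min", "condition", "dose", "value"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        df = pd.read_csv(path)
        return cls(
            [
                Observation(r.protein, float(r.t_min), r.condition, float(r.dose), float(r.value))
                for r in df.itertuples()
            ]
        )


@dataclass
class GAConfig:
    population: int = 80
    generations: int = 60
    crossover_prob: float = 0.7
    mutation_prob: float = 0.25
    mutation_sigma: float = 0.15  # relative to parameter range
    tournament_size: int = 3
    blend_alpha: float = 0.5
    elitism: int = 1
    polish: bool = True  # Nelder-Mead refinement of the GA optimum
    polish_maxfev: int = 800
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 < lo < hi")


def _predictions(params: ODEParams, obs: ObservationSet) -> np.ndarray:
    """Model values Xhat_it(theta), one integration per distinct condition."""
    cache: dict[tuple, np.ndarray] = {}
    out = np.empty(len(obs))
    times = np.array(sorted({o.t_min for o in obs} | {0.0}))
    for j, o in enumerate(obs):
        key = (o.condition, o.dose)
        if key not in cache:
            lig = (
                LigandInput(wnt5a=o.dose)
                if o.condition == "wnt5a"
                else LigandInput(egf=o.dose)
            )
            cache[key] = integrate(
                params, lig, t_grid=times, init=SignalingState(), rtol=1e-6, atol=1e-9
            )
        traj = cache[key]
        ti = int(np.searchsorted(times, o.t_min))
        out[j] = traj[ti, _PROTEIN_COL[o.protein]]
    return out


def objective(params: ODEParams, obs: ObservationSet) -> float:
    """L1 misfit between observations and model predictions.

    Integration failures yield +inf so the GA simply discards the
    offending candidate.
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    try:
        pred = _predictions(params, obs)
    except (IntegrationError, ValueError):
        return float("inf")
    vals = np.array([o.value for o in obs])
    return float(np.sum(np.abs(vals - pred)))


def generate_synthetic_observations(
    true_params: ODEParams,
    conditions: Sequence[tuple[str, float]] = (("wnt5a", 1.0), ("egf", 1.0)),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ObservationSet:
    """Surrogate observation tables in the single-ligand design.

    For each ``(condition, dose)`` the cascade is integrated from a fully
    inactive state and sampled at the design time points (Skp2 only at 30
    and 60 min); additive Gaussian noise of scale ``noise_sd`` is applied
    and the result clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    entries = []
    times = np.asarray(OBSERVATION_TIMES)
    for condition, dose in conditions:
        lig = LigandInput(wnt5a=dose) if condition == "wnt5a" else LigandInput(egf=dose)
        traj = integrate(true_params, lig, t_grid=times)
        for protein in PROTEINS:
            use = SKP2_TIMES if protein == "skp2" else OBSERVATION_TIMES
            for t in use:
                ti = int(np.searchsorted(times, t))
                v = traj[ti, _PROTEIN_COL[protein]]
                if noise_sd > 0:
                    v += rng.normal(0.0, noise_sd)
                entries.append(
                    Observation(protein, float(t), condition, dose, max(0.0, float(v)))
                )
    return ObservationSet(entries)


def _clip_to_bounds(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lo), hi)


def fit_ga(obs: ObservationSet, cfg: GAConfig | None = None):
    """Estimate the cascade parameters by a real-coded GA.

    Returns ``(ODEParams, trace)`` where ``trace`` is the best objective
    value after each generation (non-increasing thanks to elitism).  The
    whole run is deterministic given ``cfg.seed``.
    """
    if len(obs) == 0:
        raise ValueError("empty observation set")
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([cfg.bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([cfg.bounds[n][1] for n in PARAM_NAMES])
    span = hi - lo
    npar = len(PARAM_NAMES)

    pop = lo + rng.random((cfg.population, npar)) * span
    fit = np.array([objective(ODEParams.from_array(ind), obs) for ind in pop])
    trace = [float(fit.min())]

    for _ in range(cfg.generations):
        order = np.argsort(fit)
        elite = pop[order[: cfg.elitism]].copy()
        # tournament selection
        contenders = rng.integers(0, cfg.population, (cfg.population, cfg.tournament_size))
        winners = contenders[np.arange(cfg.population), np.argmin(fit[contenders], axis=1)]
        parents = pop[winners]
        # blend (BLX-alpha) crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, cfg.population - 1, 2):
            if rng.random() < cfg.crossover_prob:
                a, b = parents[i], parents[i + 1]
                d = np.abs(a - b)
                low = np.minimum(a, b) - cfg.blend_alpha * d
                high = np.maximum(a, b) + cfg.blend_alpha * d
                children[i] = low + rng.random(npar) * (high - low)
                children[i + 1] = low + rng.random(npar) * (high - low)
        # Gaussian mutation
        mutate = rng.random((cfg.population, npar)) < cfg.mutation_prob
        noise = rng.normal(0.0, cfg.mutation_sigma, (cfg.population, npar)) * span
        children = np.where(mutate, children + noise, children)
        children = _clip_to_bounds(children, lo, hi)
        children[: cfg.elitism] = elite  # elitism: best-so-far survives unchanged
        child_fit = np.array(
            [objective(ODEParams.from_array(ind), obs) for ind in children]
        )
        pop, fit = children, child_fit
        trace.append(float(min(trace[-1], fit.min())))

    best = pop[np.argmin(fit)]
    if cfg.polish:
        # deterministic local refinement of the GA optimum (memetic step)
        from scipy.optimize import minimize

        def _clipped_objective(x):
            return objective(
                ODEParams.from_array(_clip_to_bounds(x, lo, hi)), obs)

        res = minimize(_clipped_objective, best, method="Nelder-Mead",
                       options={"maxfev": cfg.polish_maxfev, "xatol": 1e-6,
                                "fatol": 1e-8})
        if res.fun < trace[-1]:
            best = _clip_to_bounds(res.x, lo, hi)
            trace.append(float(res.fun))
    if trace[-1] > float(min(trace)):  # pragma: no cover - defensive
        trace[-1] = float(min(trace))
    return ODEParams.from_array(best), np.array(trace)
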