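"""WNT5A/EGF-driven androgen-independent AR signaling in prostate cancer cells.

A five-species ODE cascade translates extracellular WNT5A and EGF doses
(both normalised to [0, 1], where 1 is the maximal experimental dose:
250 ng/mL WNT5A, 50 ng/mL EGF) into an androgen-independent proliferation
signal for a tumour cell:

    dERK/dt  = k1 * W/(H1+W)              - d1 * ERK
    dSkp2/dt = k2 * E/(H2+E)              - d2 * Skp2
    dAKT/dt  = k3 * Skp2/(H3+Skp2)        - d3 * AKT
    dAR/dt   = (1-D1) * k4 * ERK/(H4+ERK)
             + (1-D2) * k5 * AKT/(H5+AKT) - d4 * AR
    dProl/dt = k6 * AR/(H6+AR)            - d5 * Prol

W and E are held constant over an integration.  D1 and D2 are constant
inhibition fractions for the WNT5A branch (upstream of ERK->AR) and the
EGF branch (Skp2->AKT->AR); 1 means complete blockade.  The model output
used by the agent layer is the fold change of the proliferation signal at
a fixed horizon relative to an unstimulated cell.

Because every Hill input is constant or settles to a constant, the system
has a unique globally attracting steady state that composes in closed
form down the cascade; :func:`steady_state` implements it and the
integrator is checked against it in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LigandInput",
    "SignalingState",
    "ODEParams",
    "InhibitionState",
    "hill_activation",
    "ode_rhs",
    "integrate",
    "steady_state",
    "proliferation_fold_change",
    "steady_state_fold_change",
    "ode_sensitivity_scan",
    "trajectory_to_csv",
]

STATE_NAMES = ("erk", "skp2", "akt", "ar", "prol")


@dataclass(frozen=True)
class LigandInput:
    """Dimensionless ligand doses, 1.0 = maximal experimental dose."""

    wnt5a: float = 0.0
    egf: float = 0.0

    def __post_init__(self):
        for name in ("wnt5a", "egf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} dose must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class InhibitionState:
    """Branch inhibition fractions: 0 = no drug, 1 = complete blockade."""

    d1_block: float = 0.0
    d2_block: float = 0.0

    def __post_init__(self):
        for name in ("d1_block", "d2_block"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SignalingState:
    erk: float = 0.0
    skp2: float = 0.0
    akt: float = 0.0
    ar: float = 0.0
    prol: float = 0.0

    def __post_init__(self):
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} activity must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SignalingState":
        return cls(**dict(zip(STATE_NAMES, (float(v) for v in arr))))


@dataclass(frozen=True)
class ODEParams:
    """Rate constants of the signaling cascade.

    k: maximal activation rates (1/min); H: dimensionless half-saturation
    constants; d: first-order decay rates (1/min).  Six distinct H values
    are used, one per Hill term.  All entries must be strictly positive.
    """

    k1: float = 0.12
    k2: float = 0.12
    k3: float = 0.12
    k4: float = 0.12
    k5: float = 0.0192
    k6: float = 0.12
    H1: float = 0.3
    H2: float = 0.3
    H3: float = 0.3
    H4: float = 0.3
    H5: float = 0.3
    H6: float = 0.3
    d1: float = 0.12
    d2: float = 0.12
    d3: float = 0.12
    d4: float = 0.12
    d5: float = 0.12

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {v}")

    def as_dict(self) -> dict:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([asdict(self)[n] for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ODEParams":
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in arr))))


PARAM_NAMES = tuple(asdict(ODEParams()).keys())


def hill_activation(x: float, H: float):
    """Saturating activation x/(H + x); strictly increasing, -> 1 as x -> inf."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_activation requires x >= 0")
    if H <= 0:
        raise ValueError("hill_activation requires H > 0")
    out = x / (H + x)
    return float(out) if out.ndim == 0 else out


def ode_rhs(
    state: SignalingState | np.ndarray,
    params: ODEParams,
    ligands: LigandInput,
    inhib: InhibitionState = InhibitionState(),
) -> np.ndarray:
    """Time derivative of (erk, skp2, akt, ar, prol)."""
    if isinstance(state, SignalingState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    p = params
    erk, skp2, akt, ar, prol = y
    return np.array(
        [
            p.k1 * hill_activation(ligands.wnt5a, p.H1) - p.d1 * erk,
            p.k2 * hill_activation(ligands.egf, p.H2) - p.d2 * skp2,
            p.k3 * hill_activation(skp2, p.H3) - p.d3 * akt,
            (1.0 - inhib.d1_block) * p.k4 * hill_activation(erk, p.H4)
            + (1.0 - inhib.d2_block) * p.k5 * hill_activation(akt, p.H5)
            - p.d4 * ar,
            p.k6 * hill_activation(ar, p.H6) - p.d5 * prol,
        ]
    )


class IntegrationError(RuntimeError):
    """Raised when the stiff IVP solver fails; carries the parameter context."""


def integrate(
    params: ODEParams,
    ligands: LigandInput,
    inhib: InhibitionState = InhibitionState(),
    t_grid: Sequence[float] | None = None,
    init: SignalingState = SignalingState(),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the cascade on ``t_grid`` (minutes, increasing from 0).

    Returns an array of shape (len(t_grid), 5) with columns ordered as
    :data:`STATE_NAMES`.  Tiny negative round-off is clipped to zero; the
    dynamics themselves cannot cross zero from a non-negative start.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 420.0, 141)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")
    sol = solve_ivp(
        lambda t, y: ode_rhs(y, params, ligands, inhib),
        (0.0, float(t_grid[-1])),
        init.as_array(),
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver failure path
        raise IntegrationError(
            f"ODE integration failed ({sol.message}); params={params.as_dict()}, "
            f"ligands={ligands}, inhib={inhib}"
        )
    return np.clip(sol.y.T, 0.0, None)


def steady_state(
    params: ODEParams,
    ligands: LigandInput,
    inhib: InhibitionState = InhibitionState(),
):
    """Closed-form steady state, composed down the cascade.

    ERK* = (k1/d1) h(W; H1); Skp2* = (k2/d2) h(E; H2);
    AKT* = (k3/d3) h(Skp2*; H3);
    AR*  = [(1-D1) k4 h(ERK*; H4) + (1-D2) k5 h(AKT*; H5)] / d4;
    Prol* = (k6/d5) h(AR*; H6).
    """
    p = params
    erk = p.k1 / p.d1 * hill_activation(ligands.wnt5a, p.H1)
    skp2 = p.k2 / p.d2 * hill_activation(ligands.egf, p.H2)
    akt = p.k3 / p.d3 * hill_activation(skp2, p.H3)
    ar = (
        (1.0 - inhib.d1_block) * p.k4 * hill_activation(erk, p.H4)
        + (1.0 - inhib.d2_block) * p.k5 * hill_activation(akt, p.H5)
    ) / p.d4
    prol = p.k6 / p.d5 * hill_activation(ar, p.H6)
    return SignalingState(erk=erk, skp2=skp2, akt=akt, ar=ar, prol=prol)


def proliferation_fold_change(
    params: ODEParams,
    ligands: LigandInput,
    inhib: InhibitionState = InhibitionState(),
    horizon_min: float = 72.0 * 60.0,
    init: SignalingState = SignalingState(),
    basal_offset: float = 0.01,
) -> float:
    """Fold change of the proliferation signal relative to no stimulation.

    Both the stimulated and the unstimulated trajectory start from the
    same initial state and are read at ``horizon_min``.  A fixed basal
    proliferation offset (default 0.01) is added to numerator and
    denominator so that the unstimulated reference is well defined for a
    cell starting from a fully inactive cascade.
    """
    if basal_offset <= 0:
        raise ValueError("basal_offset must be > 0 to define the reference")
    grid = np.array([0.0, horizon_min])
    stim = integrate(params, ligands, inhib, grid, init=init)[-1, 4]
    base = integrate(params, LigandInput(0.0, 0.0), inhib, grid, init=init)[-1, 4]
    return (stim + basal_offset) / (base + basal_offset)


def steady_state_fold_change(
    params: ODEParams,
    wnt5a,
    egf,
    d1_block: float = 0.0,
    d2_block: float = 0.0,
    basal_offset: float = 0.01,
):
    """Vectorised steady-state version of the proliferation fold change.

    Used by the agent layer, where one fold-change evaluation is needed per
    tumour cell per step: the cascade settles within about an hour for the
    shipped parameters, so the steady state equals the finite-horizon
    readout to solver precision while avoiding an IVP solve per cell.
    """
    p = params
    w = np.clip(np.asarray(wnt5a, dtype=float), 0.0, 1.0)
    e = np.clip(np.asarray(egf, dtype=float), 0.0, 1.0)
    erk = p.k1 / p.d1 * (w / (p.H1 + w))
    skp2 = p.k2 / p.d2 * (e / (p.H2 + e))
    akt = p.k3 / p.d3 * (skp2 / (p.H3 + skp2))
    ar = (
        (1.0 - d1_block) * p.k4 * (erk / (p.H4 + erk))
        + (1.0 - d2_block) * p.k5 * (akt / (p.H5 + akt))
    ) / p.d4
    prol = p.k6 / p.d5 * (ar / (p.H6 + ar))
    return (prol + basal_offset) / basal_offset


def ode_sensitivity_scan(
    params: ODEParams,
    ligands: LigandInput,
    delta: float = 0.05,
    horizon_min: float = 72.0 * 60.0,
    basal_offset: float = 0.01,
) -> dict:
    """Perturb each rate constant by ±``delta`` (default 5%).

    Returns {parameter name: (relative change for +delta, for -delta)} of
    the proliferation fold change at the horizon.
    """
    ref = proliferation_fold_change(
        params, ligands, horizon_min=horizon_min, basal_offset=basal_offset
    )
    base = params.as_dict()
    out = {}
    for name in PARAM_NAMES:
        changes = []
        for sign in (+1.0, -1.0):
            mod = dict(base)
            mod[name] = base[name] * (1.0 + sign * delta)
            val = proliferation_fold_change(
                ODEParams(**mod),
                ligands,
                horizon_min=horizon_min,
                basal_offset=basal_offset,
            )
            changes.append((val - ref) / ref)
        out[name] = tuple(changes)
    return out


def trajectory_to_csv(t_grid, trajectory, path) -> None:
    """Write a trajectory as CSV with header ``t_min,erk,skp2,akt,ar,prol``."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(trajectory), columns=list(STATE_NAMES))
    df.insert(0, "t_min", np.asarray(t_grid, dtype=float))
    df.to_csv(path, index=False)
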