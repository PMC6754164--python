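"""Per-step behaviour rules for the cell agents in the tumour space.

Each rule turns the local microenvironment into action probabilities and
resolves them against counter-based dice (see :mod:`crpcsim.rng`), so a
cell's decision depends only on its id, the step index and the stream
seed.  Spatial moves go through :func:`propose_placement`: candidate
empty sites within a Chebyshev search radius are scored by

    M = w_dist * w_occ * w_type,   w_dist = 1/|d|,  w_occ = 1/(1+n_occ),

where ``|d|`` is the Chebyshev offset, ``n_occ`` the occupied-neighbour
count at the candidate, and ``w_type`` an optional per-neighbour-type
attraction weight (used by T cells chasing their targets).  A candidate
is drawn proportionally to the scores and then accepted with probability
min(M, 1); a fully occupied neighbourhood yields no move.  The search
radius is 2 for migration and 1 for daughter placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import rng
from .config import CTLRules, PCRules, TAMRules, TregRules
from .microenv import Lattice
from .signaling import ODEParams, steady_state_fold_change

__all__ = [
    "MoveProposal",
    "propose_placement",
    "pc_division_probability",
    "pc_death_probability",
    "pc_decide",
    "pc_resistance_switch_probability",
    "tam_recruitment_rate",
    "tam_division_probability",
    "tam_secretion_factors",
    "ctl_kill_probability",
    "treg_division_probability",
]

_CHEB = {}  # cached neighbourhood offset tables


def _offsets(R: int) -> np.ndarray:
    if R not in _CHEB:
        r = np.arange(-R, R + 1)
        g = np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)
        _CHEB[R] = g[np.any(g != 0, axis=1)]
    return _CHEB[R]


@dataclass(frozen=True)
class MoveProposal:
    origin: tuple
    candidate: tuple
    offset: int  # Chebyshev distance |d|
    occupied_count: int
    score: float  # acceptance probability M in [0, 1]


def propose_placement(
    pos,
    R: int,
    lattice: Lattice,
    u_pick: float,
    u_accept: float,
    type_weights: Optional[dict] = None,
) -> Optional[MoveProposal]:
    """Score empty candidate sites within radius R and sample one.

    ``u_pick`` selects a candidate proportionally to the scores and
    ``u_accept`` applies the acceptance probability of the chosen site.
    Returns ``None`` when no empty site exists or the move is rejected.
    """
    if R not in (1, 2):
        raise ValueError("search radius must be 1 (placement) or 2 (migration)")
    empties = lattice.empty_neighbors(pos, R)
    if len(empties) == 0:
        return None
    d = np.max(np.abs(empties - np.asarray(pos)), axis=1)
    scores = np.empty(len(empties), dtype=float)
    occs = np.empty(len(empties), dtype=int)
    for i, cand in enumerate(empties):
        occ = lattice.occupied_neighbor_count(tuple(cand), 1)
        w = (1.0 / d[i]) * (1.0 / (1.0 + occ))
        if type_weights:
            x, y, z = cand
            n = lattice.n
            xs = slice(max(0, x - 1), min(n, x + 2))
            ys = slice(max(0, y - 1), min(n, y + 2))
            zs = slice(max(0, z - 1), min(n, z + 2))
            block = lattice.occ_type[xs, ys, zs]
            for code, weight in type_weights.items():
                w *= weight ** int(np.count_nonzero(block == code))
        scores[i] = w
        occs[i] = occ
    total = scores.sum()
    if total <= 0:
        return None
    cum = np.cumsum(scores) / total
    j = int(np.searchsorted(cum, u_pick, side="right"))
    j = min(j, len(empties) - 1)
    accept = min(1.0, scores[j])
    if u_accept >= accept:
        return None
    return MoveProposal(
        origin=tuple(int(c) for c in pos),
        candidate=tuple(int(c) for c in empties[j]),
        offset=int(d[j]),
        occupied_count=int(occs[j]),
        score=float(accept),
    )


# ---------------------------------------------------------------------------
# prostate cancer cells
# ---------------------------------------------------------------------------

def pc_division_probability(
    rules: PCRules,
    ode: ODEParams,
    resistant,
    androgen_tissue: float,
    wnt5a_local,
    egf_local,
    n_pc: int,
    d1_block: float = 0.0,
    d2_block: float = 0.0,
    near_vessel=False,
):
    """Division probability per 2-h step (vectorised over cells).

    Sensitive cells proliferate through the androgen-dependent pathway
    only; resistant cells add the WNT5A/EGF-driven androgen-independent
    signal (steady-state fold change of the cascade).  A logistic
    capacity factor models nutrient limitation, and cells near a
    perfused vessel get a configurable bonus.
    """
    resistant = np.asarray(resistant, dtype=bool)
    a = androgen_tissue / (rules.h_androgen + androgen_tissue)
    p_ad = rules.p_base_ad * a
    w = np.asarray(wnt5a_local, dtype=float)
    e = np.asarray(egf_local, dtype=float)
    dose_w = w / (rules.w_ref + w)
    dose_e = e / (rules.e_ref + e)
    fold = steady_state_fold_change(
        ode, dose_w, dose_e, d1_block, d2_block, rules.basal_offset
    )
    p = np.where(resistant, p_ad + rules.p_base_ai * fold, p_ad)
    cap = max(0.0, 1.0 - n_pc / rules.capacity)
    p = p * cap
    bonus = np.where(np.asarray(near_vessel, dtype=bool), 1.0 + rules.vessel_bonus, 1.0)
    return np.clip(p * bonus, 0.0, 1.0)


def pc_death_probability(rules: PCRules, resistant, androgen_tissue: float):
    """Death probability per step: sensitive cells die faster at castrate
    androgen; resistant cells keep the basal rate."""
    resistant = np.asarray(resistant, dtype=bool)
    a = androgen_tissue / (rules.h_androgen + androgen_tissue)
    starved = rules.p_die_base + rules.p_die_castrate * (1.0 - a)
    return np.where(resistant, rules.p_die_base, starved)


def pc_decide(
    rules: PCRules,
    ode: ODEParams,
    resistant: bool,
    androgen_tissue: float,
    wnt5a_local: float,
    egf_local: float,
    n_pc: int,
    lattice: Lattice,
    pos,
    seed: int,
    step: int,
    agent_id: int,
    d1_block: float = 0.0,
    d2_block: float = 0.0,
    near_vessel: bool = False,
) -> str:
    """One tumour cell's fate this step: die / divide / migrate / persist.

    Division requires an empty site at R=1; a blocked division demotes to
    the migrate/persist path (the quiescent outcome).
    """
    u_die = rng.dice_scalar(seed, step, rng.Channels.DIE, agent_id)
    if u_die < float(pc_death_probability(rules, resistant, androgen_tissue)):
        return "die"
    p_div = float(
        pc_division_probability(
            rules, ode, resistant, androgen_tissue, wnt5a_local, egf_local,
            n_pc, d1_block, d2_block, near_vessel,
        )
    )
    u_div = rng.dice_scalar(seed, step, rng.Channels.DIVIDE, agent_id)
    if u_div < p_div:
        if len(lattice.empty_neighbors(pos, 1)) > 0:
            return "divide"
        # no room: fall through to migration/quiescence
    u_mig = rng.dice_scalar(seed, step, rng.Channels.MIGRATE, agent_id)
    if u_mig < rules.p_migrate and len(lattice.empty_neighbors(pos, 2)) > 0:
        return "migrate"
    return "persist"


def pc_resistance_switch_probability(
    rules: PCRules, t_since_castration_h: float
) -> float:
    """Per-step probability that a sensitive cell becomes resistant.

    Zero before castration; afterwards the probability ramps linearly to
    ``switch_rate`` over ``switch_ramp_h`` (AR-reactivation kinetics
    calibrated so the resistant clone dominates about two weeks after
    castration)."""
    if t_since_castration_h <= 0:
        return 0.0
    ramp = min(1.0, t_since_castration_h / rules.switch_ramp_h)
    return rules.switch_rate * ramp


# ---------------------------------------------------------------------------
# macrophages
# ---------------------------------------------------------------------------

def tam_recruitment_rate(rules: TAMRules, csf1_mean: float, plx_efficacy: float = 0.0):
    """Expected TAM recruits per step; CSF1R blockade scales the
    CSF1-driven term by (1 - efficacy)."""
    drive = csf1_mean / (rules.h_csf1 + csf1_mean)
    return rules.rec_base + (1.0 - plx_efficacy) * rules.rec_coef * drive


def tam_division_probability(rules: TAMRules, csf1_local, plx_efficacy: float = 0.0):
    c = np.asarray(csf1_local, dtype=float)
    drive = c / (rules.h_csf1 + c)
    return np.clip((1.0 - plx_efficacy) * rules.div_coef * drive, 0.0, 1.0)


def tam_secretion_factors(rules: TAMRules, androgen_deprivation: float):
    """Per-TAM IL10 and VEGF secretion rates under ADT-driven polarization.

    ``androgen_deprivation`` is ``1 - A/A0`` (0 before castration, ~0.8 at
    the castrate floor).  Androgen deprivation shifts macrophages to a
    protumorigenic M2-like secretory phenotype: basal rate times
    ``1 + coef * deprivation``.  Returns ``(il10_rate, vegf_rate)``."""
    d = float(np.clip(androgen_deprivation, 0.0, 1.0))
    il10 = rules.il10_rate * (1.0 + rules.il10_coef * d)
    vegf = rules.vegf_rate * (1.0 + rules.vegf_coef * d)
    return il10, vegf


# ---------------------------------------------------------------------------
# T cells
# ---------------------------------------------------------------------------

def ctl_kill_probability(rules: CTLRules, il10_local, suppressed=False):
    """Per-contact kill probability; IL10 lowers it, Treg arrest blocks it."""
    c = np.asarray(il10_local, dtype=float)
    p = rules.p_kill * (1.0 - rules.il10_suppress * c / (rules.h_il10 + c))
    return np.where(np.asarray(suppressed, dtype=bool), 0.0, np.clip(p, 0.0, 1.0))


def treg_division_probability(
    rules: TregRules, trail_local, il2_local, anti_il2: float = 0.0
):
    """Treg division prob: basal + TRAIL-driven + IL2-driven (neutralisable)."""
    tr = np.asarray(trail_local, dtype=float)
    il2 = np.asarray(il2_local, dtype=float)
    p = (
        rules.p_div_base
        + rules.div_trail * tr / (rules.h_trail + tr)
        + (1.0 - anti_il2) * rules.div_il2 * il2 / (rules.h_il2 + il2)
    )
    return np.clip(p, 0.0, 1.0)
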