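"""Lymph-node compartment: antigen-driven DC cycle and programmed T-cell
clonal expansion.

Dying tumour cells release antigen that is engulfed by dendritic cells.
A DC spawned at time t migrates for 12 h, matures on arrival in the node,
and can stimulate naive T cells from 12 h after maturation (t + 24 h)
until it dies at t + 48 h.  Each stimulated naive T cell commits to a
programmed response: no division during the first ~20 h of stimulation,
then one division every ``division_period_h`` until a clone-specific
generation target g drawn uniformly from {7..10}, yielding exactly 2**g
cells that acquire effector function.  Completed cohorts join the node's
effector pool, persist with low-rate memory proliferation, and leave for
the tumour through the lymphatic vessel at a rate-limited trickle.
Regulatory T cells run the same program (their own clones); their
node-resident expansion is additionally driven by IL-2 from activated
CD8 cells, which is what IL-2 neutralisation switches off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LymphRules

__all__ = ["CloneCohort", "LymphNode"]

CTL_KIND = 0
TREG_KIND = 1


@dataclass
class CloneCohort:
    """One activated naive T cell undergoing programmed expansion."""

    kind: int  # CTL_KIND or TREG_KIND
    stim_h: float = 0.0  # antigenic stimulation received so far
    generation: int = 0
    target_generation: int = 8
    count: int = 1

    def completed(self) -> bool:
        return self.generation >= self.target_generation


class LymphNode:
    """Well-mixed lymph-node compartment.

    Tracks the DC population (by clock), expanding clones, and the
    post-expansion effector pools.  All stochastic draws come from the
    generator handed to each call, so the engine controls determinism.
    """

    def __init__(self, rules: LymphRules):
        self.rules = rules
        self.dc_clocks: list[float] = []
        self.clones: list[CloneCohort] = []
        self.ctl_pool = 0
        self.treg_pool = 0
        # conservation bookkeeping: every effector T cell is created once
        # and is in the node, in the tumour, or dead
        self.created = {CTL_KIND: 0, TREG_KIND: 0}
        self.died = {CTL_KIND: 0, TREG_KIND: 0}
        self.infiltrated = {CTL_KIND: 0, TREG_KIND: 0}

    # -- DC cycle ------------------------------------------------------
    def n_presenting(self) -> int:
        """DCs in the presenting state (>= 12 h since spawn, < 48 h)."""
        return sum(1 for c in self.dc_clocks if 12.0 <= c < 48.0)

    def n_stimulating(self) -> int:
        """Presenting DCs past the 12-h immune-response latency (>= 24 h)."""
        return sum(1 for c in self.dc_clocks if 24.0 <= c < 48.0)

    def dc_cycle(self, dying_pc_antigen: float, dt_h: float,
                 gen: np.random.Generator, dc_efficiency: float = 1.0):
        """Antigen uptake spawns migrating DCs; clocks advance; 48-h death.

        ``dc_efficiency`` scales antigen processing: the engine lowers it
        with the tumour IL10 level (TAM-derived IL10 impairs DC
        maturation), which is what exhausts the response late on."""
        if dying_pc_antigen < 0:
            raise ValueError("antigen counter must be >= 0")
        n_new = gen.poisson(
            dying_pc_antigen * self.rules.dc_per_antigen * dc_efficiency)
        self.dc_clocks = [c + dt_h for c in self.dc_clocks if c + dt_h < 48.0]
        self.dc_clocks.extend([0.0] * int(n_new))
        return self.n_stimulating()

    # -- programmed expansion ------------------------------------------
    def t_activate_expand(self, dt_h: float, gen: np.random.Generator) -> None:
        """Activate new clones and advance the expansion program."""
        r = self.rules
        n_stim = self.n_stimulating()
        if n_stim > 0:
            # activation is niche-limited: saturates at high DC numbers
            eff = n_stim / (1.0 + n_stim / r.stim_saturation)
            n_new = gen.poisson(r.clone_rate * eff)
            for _ in range(int(n_new)):
                kind = TREG_KIND if gen.random() < r.treg_clone_fraction else CTL_KIND
                target = int(gen.integers(r.generation_min, r.generation_max + 1))
                self.clones.append(CloneCohort(kind=kind, target_generation=target))
        finished = []
        for clone in self.clones:
            clone.stim_h += dt_h
            while (
                not clone.completed()
                and clone.stim_h
                >= r.stimulation_h + (clone.generation + 1) * r.division_period_h
            ):
                clone.generation += 1
                clone.count *= 2
            if clone.completed():
                finished.append(clone)
        for clone in finished:
            self.clones.remove(clone)
            self.created[clone.kind] += clone.count
            if clone.kind == CTL_KIND:
                self.ctl_pool += clone.count
            else:
                self.treg_pool += clone.count
        # memory maintenance, node-resident death, IL2-driven Treg division
        il2 = self.ctl_pool / (self.ctl_pool + r.h_il2_ln) if self.ctl_pool else 0.0
        for kind in (CTL_KIND, TREG_KIND):
            pool = self.ctl_pool if kind == CTL_KIND else self.treg_pool
            if pool <= 0 and kind == CTL_KIND:
                continue
            p_div = r.memory_div
            if kind == TREG_KIND:
                p_div += (1.0 - self.anti_il2) * r.treg_il2_div * il2
            births = gen.binomial(pool, min(1.0, p_div)) if pool > 0 else 0
            # niche crowding: death accelerates as the pool outgrows the node
            p_die = r.ln_death * (1.0 + pool / r.ln_niche)
            deaths = gen.binomial(pool, min(1.0, p_die)) if pool > 0 else 0
            if kind == TREG_KIND and r.initial_ln_treg > 0:
                # natural Tregs are kept near their homeostatic set-point
                # by thymic output / niche-limited proliferation
                gap = r.initial_ln_treg - pool
                if gap > 0:
                    topup = gen.poisson(r.treg_homeostasis * gap)
                    births += int(topup)
            self.created[kind] += int(births)
            self.died[kind] += int(deaths)
            pool += int(births) - int(deaths)
            if kind == CTL_KIND:
                self.ctl_pool = max(0, pool)
            else:
                self.treg_pool = max(0, pool)

    anti_il2: float = 0.0  # set by the engine's treatment layer

    # -- infiltration ---------------------------------------------------
    def draw_infiltration(self, gen: np.random.Generator) -> tuple[int, int]:
        """Number of (CTL, Treg) effectors leaving for the tumour this step.

        A rate-limited random subset of each pool; cells that cannot be
        placed are returned to the pool by the engine (queued, retried)."""
        r = self.rules
        n_ctl = min(
            r.infiltration_cap, gen.binomial(self.ctl_pool, r.infiltration_rate)
        ) if self.ctl_pool else 0
        n_treg = min(
            r.infiltration_cap,
            gen.binomial(self.treg_pool, r.treg_infiltration_rate)
        ) if self.treg_pool else 0
        return int(n_ctl), int(n_treg)

    def commit_infiltration(self, kind: int, n: int) -> None:
        if kind == CTL_KIND:
            self.ctl_pool -= n
        else:
            self.treg_pool -= n
        self.infiltrated[kind] += n

    def conservation_ok(self, tumor_alive: dict, tumor_dead: dict) -> bool:
        """created == node pool + expanding? no: clones are pre-effector.
        Checks created = pool + infiltrated - (returned) and that the
        tumour-side ledger closes: infiltrated = alive-in-tumour + dead-in-tumour."""
        for kind, pool in ((CTL_KIND, self.ctl_pool), (TREG_KIND, self.treg_pool)):
            if self.created[kind] != (
                pool + self.died[kind] + self.infiltrated[kind]
            ):
                return False
            if self.infiltrated[kind] != tumor_alive.get(kind, 0) + tumor_dead.get(kind, 0):
                return False
        return True
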