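"""Tumour-induced angiogenesis: sprouting, chemotaxis, branching,
anastomosis.

The avascular tumour triggers angiogenesis once its effective diameter
exceeds a critical value (~2 mm).  Sprouts then grow from a pre-existing
parent vessel: seed positions along the vessel follow a truncated normal
density that vanishes in the first and last 14% of its length; tips
perform a VEGF-gradient-biased random walk on the lattice, consume VEGF
locally, may branch once their tip age exceeds 18 h (the newly formed
sprout needs time to accumulate endothelial cells; higher local VEGF
lowers that requirement, i.e. raises the branching probability), and a
tip stepping onto another sprout's path fuses with it (anastomosis) and
goes inactive.  Tips never revisit their own path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AngioRules

__all__ = [
    "Sprout",
    "export_network_csv",
    "maybe_start_angiogenesis",
    "sample_sprout_positions",
    "init_sprouts",
    "tip_step",
    "branch",
    "anastomose",
]

_FACES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass
class Sprout:
    path: list  # ordered site tuples, root first
    tip_age_h: float = 0.0
    active: bool = True
    _visited: set = field(default_factory=set)

    def __post_init__(self):
        self._visited.update(self.path)

    @property
    def tip(self):
        return self.path[-1]

    def extend(self, site) -> None:
        self.path.append(site)
        self._visited.add(site)

    def connected(self) -> bool:
        """Path is a chain of lattice neighbours (Chebyshev distance 1)."""
        p = np.asarray(self.path)
        if len(p) < 2:
            return True
        return bool(np.all(np.max(np.abs(np.diff(p, axis=0)), axis=1) <= 1))


def export_network_csv(sprouts: list["Sprout"], path) -> None:
    """Per-sprout site paths: ``sprout_id,step,x,y,z,active``."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sprout_id", "step", "x", "y", "z", "active"])
        for i, s in enumerate(sprouts):
            for j, (x, y, z) in enumerate(s.path):
                w.writerow([i, j, x, y, z, int(s.active)])


def maybe_start_angiogenesis(
    diameter_sites: float,
    onset: bool,
    rules: AngioRules,
    spacing_um: float,
) -> bool:
    """One-way onset flag: True once the tumour diameter reaches the
    critical value; regression below threshold never resets it."""
    if onset:
        return True
    return diameter_sites * spacing_um / 1000.0 >= rules.onset_diameter_mm


def sample_sprout_positions(
    n: int, vessel_length: int, rules: AngioRules, gen: np.random.Generator
) -> np.ndarray:
    """Seed x-positions along the parent vessel.

    Truncated normal (mean ``sprout_mean_frac * L``, sd ``sprout_sd_frac
    * L``), rejected outside the open interval excluding the first and
    last ``sprout_exclusion_frac`` of the vessel — the margins carry zero
    initiation density."""
    L = vessel_length
    lo, hi = rules.sprout_exclusion_frac * L, (1.0 - rules.sprout_exclusion_frac) * L
    out = []
    while len(out) < n:
        x = int(round(gen.normal(rules.sprout_mean_frac * L,
                                 rules.sprout_sd_frac * L)))
        if lo < x < hi:
            out.append(x)
    return np.array(out)


def init_sprouts(
    lattice_n: int, rules: AngioRules, gen: np.random.Generator
) -> list[Sprout]:
    """Seed sprouts on the parent vessel (the x-axis line at y=0, z=n//2);
    each starts with a first segment one site into the tissue (y=1)."""
    xs = sample_sprout_positions(rules.n_sprouts, lattice_n, rules, gen)
    z0 = lattice_n // 2
    return [Sprout(path=[(int(x), 0, z0), (int(x), 1, z0)]) for x in xs]


def tip_step(
    sprout: Sprout,
    vegf: np.ndarray,
    occupied_vessel: set,
    rules: AngioRules,
    gen: np.random.Generator,
    dt_h: float = 2.0,
):
    """Advance one tip by at most one site.

    Candidate face-neighbours (never the sprout's own path) are scored by
    ``grad_weight * (VEGF(candidate) - VEGF(tip)) + noise * U``; the best
    candidate is taken with probability ``p_move``.  Returns the site of
    an anastomosis (a candidate already on another sprout's path) or
    ``None``.  A boxed-in tip stalls while its age keeps accruing.
    """
    sprout.tip_age_h += dt_h
    if not sprout.active:
        return None
    if gen.random() >= rules.p_move:
        return None
    n = vegf.shape[0]
    tip = np.asarray(sprout.tip)
    cands = tip + _FACES
    ok = np.all((cands >= 0) & (cands < n), axis=1)
    cands = cands[ok]
    cands = [tuple(int(v) for v in c) for c in cands]
    cands = [c for c in cands if c not in sprout._visited]
    if not cands:
        return None
    here = vegf[tuple(tip)]
    scores = [
        rules.grad_weight * (vegf[c] - here) + rules.noise * gen.random()
        for c in cands
    ]
    best = cands[int(np.argmax(scores))]
    sprout.extend(best)
    if best in occupied_vessel:
        sprout.active = False  # loop closed
        return best
    return None


def branch(
    sprout: Sprout,
    vegf: np.ndarray,
    rules: AngioRules,
    gen: np.random.Generator,
) -> Sprout | None:
    """Branch from a tip aged >= 18 h with probability
    ``min(1, basal + coef * VEGF_local)``; both tip ages reset."""
    if not sprout.active or sprout.tip_age_h < rules.branch_age_h:
        return None
    p = min(1.0, rules.branch_basal + rules.branch_coef * float(vegf[sprout.tip]))
    if gen.random() >= p:
        return None
    sprout.tip_age_h = 0.0
    return Sprout(path=[sprout.tip], tip_age_h=0.0)


def anastomose(sprouts: list[Sprout]) -> list[Sprout]:
    """Deactivate any sprout whose tip sits on another sprout's path."""
    for i, s in enumerate(sprouts):
        if not s.active:
            continue
        tip = s.tip
        for j, other in enumerate(sprouts):
            if i != j and tip in other._visited:
                s.active = False
                break
    return sprouts
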