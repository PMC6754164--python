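"""Tumour-space lattice, cytokine fields, and the androgen compartment.

The tumour space is a 3D cubic lattice with hard volume exclusion (at most
one cell agent per site).  Each diffusible cytokine (WNT5A, EGF, CSF1,
VEGF, IL10, IL2, TRAIL) lives on the same lattice as a non-negative
concentration field updated by per-site secretion, explicit
finite-difference diffusion with zero-flux (Neumann) boundaries,
first-order decay, and clipped consumption.  Concentrations are in
arbitrary units; diffusion coefficients are expressed in lattice units
(site^2 per hour) so the explicit-scheme stability bound D*dt <= 1/6 is
checked directly and violated steps are automatically substepped.

Androgen is modelled as two well-mixed scalars (blood and tissue level,
as fractions of the pre-treatment value) rather than a spatial field:
castration relaxes them continuously toward ~10% (blood) and ~20%
(tissue) of baseline, and castration-resistant tumour cells add a tissue
DHT-synthesis source that can raise the tissue level back toward a
configurable plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPECIES",
    "Lattice",
    "CytokineField",
    "AndrogenState",
    "laplacian_neumann",
    "diffuse_decay",
    "secrete_consume",
    "apply_castration",
    "update_crpc_androgen",
]

SPECIES = ("wnt5a", "egf", "csf1", "vegf", "il10", "il2", "trail")

# occupancy type codes
EMPTY = -1
PC = 0
TAM = 1
CTL = 2
TREG = 3
EC = 4

TYPE_NAMES = {PC: "pc", TAM: "tam", CTL: "ctl", TREG: "treg", EC: "ec"}


class Lattice:
    """Cubic occupancy lattice for the tumour space.

    ``occ_type`` holds the agent type code per site (-1 empty) and
    ``occ_id`` the unique agent id.  The parent vessel is a line of sites
    on the x-axis at the y=0 face; cell agents never occupy vessel sites.
    """

    def __init__(self, n: int = 50, spacing_um: float = 150.0):
        if n < 5:
            raise ValueError("lattice edge must be at least 5 sites")
        self.n = int(n)
        self.spacing_um = float(spacing_um)
        self.occ_type = np.full((n, n, n), EMPTY, dtype=np.int8)
        self.occ_id = np.full((n, n, n), -1, dtype=np.int64)
        # incrementally maintained 27-neighbourhood tallies (centre included):
        # total occupancy, tumour cells, cytotoxic T cells
        self.n27_occ = np.zeros((n, n, n), dtype=np.int16)
        self.n27_pc = np.zeros((n, n, n), dtype=np.int16)
        self.n27_ctl = np.zeros((n, n, n), dtype=np.int16)
        # parent vessel: line along x at y=0, z=n//2 (blocked for cells)
        self.parent_vessel = np.zeros((n, n, n), dtype=bool)
        self.parent_vessel[:, 0, n // 2] = True
        # lymphatic entry face: T cells arriving from the lymph node enter
        # through empty sites in the x = n-1 plane
        self.entry_plane = self.n - 1

    # -- queries -------------------------------------------------------
    def in_bounds(self, p) -> bool:
        return all(0 <= c < self.n for c in p)

    def is_empty(self, p) -> bool:
        x, y, z = p
        return self.occ_type[x, y, z] == EMPTY and not self.parent_vessel[x, y, z]

    def empty_neighbors(self, p, R: int) -> np.ndarray:
        """Empty sites within Chebyshev distance R (26-neighbourhood at R=1)."""
        x, y, z = p
        n = self.n
        xs = slice(max(0, x - R), min(n, x + R + 1))
        ys = slice(max(0, y - R), min(n, y + R + 1))
        zs = slice(max(0, z - R), min(n, z + R + 1))
        block_empty = (self.occ_type[xs, ys, zs] == EMPTY) & ~self.parent_vessel[xs, ys, zs]
        idx = np.argwhere(block_empty)
        idx += [xs.start, ys.start, zs.start]
        # exclude the origin itself
        keep = ~np.all(idx == [x, y, z], axis=1)
        return idx[keep]

    def occupied_neighbor_count(self, p, R: int = 1) -> int:
        x, y, z = p
        n = self.n
        xs = slice(max(0, x - R), min(n, x + R + 1))
        ys = slice(max(0, y - R), min(n, y + R + 1))
        zs = slice(max(0, z - R), min(n, z + R + 1))
        occ = int(np.count_nonzero(self.occ_type[xs, ys, zs] != EMPTY))
        if self.occ_type[x, y, z] != EMPTY:
            occ -= 1
        return occ

    # -- mutation ------------------------------------------------------
    def _bump(self, p, type_code: int, delta: int) -> None:
        x, y, z = p
        n = self.n
        sl = (slice(max(0, x - 1), min(n, x + 2)),
              slice(max(0, y - 1), min(n, y + 2)),
              slice(max(0, z - 1), min(n, z + 2)))
        self.n27_occ[sl] += delta
        if type_code == PC:
            self.n27_pc[sl] += delta
        elif type_code == CTL:
            self.n27_ctl[sl] += delta

    def place(self, p, type_code: int, agent_id: int) -> None:
        x, y, z = p
        if self.occ_type[x, y, z] != EMPTY:
            raise RuntimeError(f"site {p} already occupied (exclusion violated)")
        if self.parent_vessel[x, y, z]:
            raise RuntimeError(f"site {p} belongs to the parent vessel")
        self.occ_type[x, y, z] = type_code
        self.occ_id[x, y, z] = agent_id
        self._bump(p, type_code, 1)

    def clear(self, p) -> None:
        x, y, z = p
        code = int(self.occ_type[x, y, z])
        self.occ_type[x, y, z] = EMPTY
        self.occ_id[x, y, z] = -1
        if code != EMPTY:
            self._bump(p, code, -1)

    def move(self, src, dst) -> None:
        x, y, z = src
        t, i = self.occ_type[x, y, z], self.occ_id[x, y, z]
        self.clear(src)
        self.place(dst, int(t), int(i))


@dataclass
class CytokineField:
    """One diffusible species on the lattice."""

    species: str
    n: int = 50
    diffusion: float = 0.1  # site^2 / h
    decay: float = 0.05  # 1/h
    conc: np.ndarray = None  # set in __post_init__
    dtype: type = np.float64

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.diffusion < 0 or self.decay < 0:
            raise ValueError("diffusion and decay rates must be >= 0")
        if self.conc is None:
            self.conc = np.zeros((self.n, self.n, self.n), dtype=self.dtype)

    def total(self) -> float:
        return float(self.conc.sum())


def laplacian_neumann(f: np.ndarray) -> np.ndarray:
    """7-point discrete Laplacian with zero-flux boundaries.

    An out-of-domain neighbour is replaced by the edge value itself, so
    nothing crosses the boundary and total mass is conserved exactly.
    """
    out = np.zeros_like(f)
    for ax in range(f.ndim):
        lead = [slice(None)] * f.ndim
        lag = [slice(None)] * f.ndim
        lead[ax] = slice(1, None)
        lag[ax] = slice(None, -1)
        d = f[tuple(lead)] - f[tuple(lag)]
        out[tuple(lag)] += d
        out[tuple(lead)] -= d
    return out


try:  # compiled stencil kernel; the numpy path below is the fallback
    from numba import njit

    @njit(cache=False)
    def _ftcs_step(f, alpha):
        nx, ny, nz = f.shape
        out = np.empty_like(f)
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                for k in range(nz):
                    km = k - 1 if k > 0 else 0
                    kp = k + 1 if k < nz - 1 else nz - 1
                    s = (f[im, j, k] + f[ip, j, k] + f[i, jm, k] + f[i, jp, k]
                         + f[i, j, km] + f[i, j, kp] - 6.0 * f[i, j, k])
                    out[i, j, k] = f[i, j, k] + alpha * s
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def diffuse_decay(fld: CytokineField, dt_h: float) -> CytokineField:
    """Explicit diffusion + exponential decay over ``dt_h`` hours.

    The FTCS step is stable for D*dt <= 1/6 (lattice units); larger steps
    are split into the minimal number of equal substeps satisfying the
    bound, never run unstably.
    """
    if dt_h < 0:
        raise ValueError("dt must be >= 0")
    if not fld.conc.any():
        return fld
    D = fld.diffusion
    if D > 0 and dt_h > 0:
        nsub = max(1, int(np.ceil(D * dt_h / (1.0 / 6.0))))
        alpha = fld.conc.dtype.type(D * dt_h / nsub)
        for _ in range(nsub):
            if _HAVE_NUMBA:
                fld.conc = _ftcs_step(fld.conc, alpha)
            else:
                fld.conc += alpha * laplacian_neumann(fld.conc)
    if fld.decay > 0 and dt_h > 0:
        fld.conc *= fld.conc.dtype.type(np.exp(-fld.decay * dt_h))
    np.clip(fld.conc, 0.0, None, out=fld.conc)
    return fld


def secrete_consume(
    fld: CytokineField,
    secretion_positions: np.ndarray | None,
    secretion_rate: float,
    dt_h: float,
    consumption_positions: np.ndarray | None = None,
    consumption_rate: float = 0.0,
) -> CytokineField:
    """Add ``rate * dt`` at secreting sites; remove (clipped) at consumers."""
    c = fld.conc
    if secretion_positions is not None and len(secretion_positions) and secretion_rate:
        pos = np.asarray(secretion_positions)
        np.add.at(c, (pos[:, 0], pos[:, 1], pos[:, 2]), secretion_rate * dt_h)
    if (
        consumption_positions is not None
        and len(consumption_positions)
        and consumption_rate
    ):
        pos = np.asarray(consumption_positions)
        np.add.at(c, (pos[:, 0], pos[:, 1], pos[:, 2]), -consumption_rate * dt_h)
        np.clip(c, 0.0, None, out=c)
    return fld


def export_field_snapshot(fld: CytokineField, prefix, t_h: float) -> None:
    """Write a field as a flat binary array plus a JSON sidecar."""
    import json

    arr = np.ascontiguousarray(fld.conc, dtype=np.float32)
    arr.tofile(f"{prefix}.raw")
    sidecar = {
        "species": fld.species,
        "dims": list(arr.shape),
        "dtype": "float32",
        "order": "C",
        "t_h": float(t_h),
        "diffusion": fld.diffusion,
        "decay": fld.decay,
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def export_slice_csv(fld: CytokineField, path, y: int) -> None:
    """Write the concentration slice at the given y plane as CSV."""
    np.savetxt(path, fld.conc[:, y, :], delimiter=",", fmt="%.6g")


@dataclass
class AndrogenState:
    """Two-compartment androgen level as fractions of pre-treatment."""

    blood: float = 1.0
    tissue: float = 1.0
    baseline_blood: float = 1.0
    baseline_tissue: float = 1.0
    castrated: bool = False
    castration_time_h: float = float("nan")
    blood_floor: float = 0.10  # post-castration fraction of baseline
    tissue_floor: float = 0.20
    relax_tau_h: float = 48.0  # castration relaxation time constant
    crpc_synthesis_rate: float = 0.0  # tissue units per resistant cell per hour
    crpc_plateau: float = 0.65  # cap on DHT-restored tissue androgen


def apply_castration(a: AndrogenState, t_h: float) -> AndrogenState:
    """Flag castration at ``t_h``; levels then relax continuously.

    Levels are untouched at the castration instant (no jump); a second
    call is a warned no-op.
    """
    if a.castrated:
        warnings.warn("castration applied twice; ignoring the second event")
        return a
    a.castrated = True
    a.castration_time_h = float(t_h)
    return a


def update_crpc_androgen(
    a: AndrogenState, resistant_pc_count: int, dt_h: float
) -> AndrogenState:
    """Advance androgen by ``dt_h`` hours.

    Post-castration, blood and tissue relax exponentially toward their
    castrate floors; castration-resistant cells add a tissue source
    proportional to their number, capped at ``crpc_plateau``.  Before
    castration the levels hold at baseline.
    """
    if not a.castrated:
        return a
    if a.relax_tau_h <= 0:
        step = 1.0
    else:
        step = 1.0 - float(np.exp(-dt_h / a.relax_tau_h))
    a.blood += (a.blood_floor * a.baseline_blood - a.blood) * step
    a.tissue += (a.tissue_floor * a.baseline_tissue - a.tissue) * step
    if resistant_pc_count > 0 and a.crpc_synthesis_rate > 0:
        cap = max(a.crpc_plateau * a.baseline_tissue, a.tissue)
        a.tissue = min(cap, a.tissue + a.crpc_synthesis_rate * resistant_pc_count * dt_h)
    return a
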