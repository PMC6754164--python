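"""Simulation configuration: every rate the model consumes, in one tree.

All probabilities are per 2-hour decision step unless stated otherwise;
cytokine amounts are in arbitrary concentration units; diffusion
coefficients are in lattice units (site^2/h) and decay rates in 1/h.
Defaults are the shipped calibration of the model (the parameter set the
package's reference experiments are run with); loading a config file
materialises these defaults for every key the file does not override, so
a loaded configuration is always complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .signaling import ODEParams

__all__ = [
    "PCRules",
    "TAMRules",
    "CTLRules",
    "TregRules",
    "LymphRules",
    "AngioRules",
    "AndrogenConfig",
    "FieldConfig",
    "EventTimeline",
    "TreatmentRegimen",
    "SimulationConfig",
    "KEY_PARAMETERS",
]


@dataclass
class PCRules:
    """Prostate-cancer cell behaviour."""

    p_base_ad: float = 0.0205  # max androgen-driven division prob / step
    p_base_ai: float = 6.2e-4  # scales the signaling-cascade fold change
    h_androgen: float = 0.30  # half-saturation of AR vs tissue androgen
    p_die_base: float = 0.0020  # basal death prob / step
    p_die_castrate: float = 0.016  # extra death of sensitive cells at zero androgen
    p_migrate: float = 0.02  # migration attempt prob / step (R = 2)
    switch_rate: float = 0.0025  # resistance switch prob / step at full ramp
    switch_ramp_h: float = 168.0  # linear ramp of the switch prob after castration
    capacity: float = 8600.0  # nutrient-limited logistic capacity (cells)
    vessel_bonus: float = 0.15  # division bonus within vessel_radius of a vessel
    vessel_radius: int = 5  # sites
    w_ref: float = 0.6  # WNT5A field units giving dose 0.5
    e_ref: float = 0.6  # EGF field units giving dose 0.5
    basal_offset: float = 0.01  # basal proliferation signal (fold-change floor)
    csf1_rate: float = 0.035  # CSF1 secretion per PC per hour
    csf1_induction: float = 3.1  # ADT induction: rate * (1 + a*(1 - A/A0))
    trail_rate: float = 0.02  # TRAIL secretion per resistant PC per hour
    trail_rate_sensitive: float = 0.0003
    vegf_rate: float = 0.004  # VEGF secretion per PC per hour


@dataclass
class TAMRules:
    """Tumour-associated macrophage behaviour (fast-turnover population)."""

    p_die: float = 0.042  # death prob / step (half-life ~1.6 days)
    div_coef: float = 0.054  # division prob = div_coef * hill(csf1, h_csf1)
    h_csf1: float = 0.07  # half-saturation, CSF1 field units
    rec_coef: float = 0.7  # expected recruits / step = rec_coef * hill(csf1)
    rec_base: float = 0.02  # CSF1-independent recruitment floor
    egf_rate: float = 0.020  # EGF secretion per TAM per hour
    il10_rate: float = 0.004  # basal IL10 secretion per TAM per hour
    il10_coef: float = 3.2  # M2 polarization: rate * (1 + coef * (1 - A/A0))
    vegf_rate: float = 0.008
    vegf_coef: float = 0.70
    wnt5a_rate: float = 0.002  # TAMs also secrete WNT5A


@dataclass
class CTLRules:
    """Cytotoxic CD8+ T cell behaviour in the tumour space."""

    p_die: float = 0.020  # death prob / step in the tumour
    p_kill: float = 0.02  # per-contact kill prob, before IL10 modulation
    il10_suppress: float = 0.9  # kill *= (1 - s * hill(il10, h_il10))
    h_il10: float = 0.25
    p_move: float = 0.7  # chemotactic move attempt prob / step
    chase_bias: float = 1.5  # weighting toward PC-dense candidate sites
    il2_rate: float = 0.010  # IL2 secretion per tumour CTL per hour


@dataclass
class TregRules:
    """Regulatory T cell behaviour."""

    p_die: float = 0.008
    p_div_base: float = 0.001
    div_trail: float = 0.016  # division prob += div_trail * hill(trail)
    h_trail: float = 0.15
    div_il2: float = 0.009  # division prob += div_il2 * hill(il2)
    h_il2: float = 0.4
    suppress_radius: int = 2  # Chebyshev radius of CTL suppression
    suppress_prob: float = 0.5  # prob of arresting a CTL in radius / step
    p_kill_ctl: float = 0.09  # small apoptosis induction prob
    p_move: float = 0.5
    chase_bias: float = 1.2  # weighting toward CTL-dense candidate sites
    wnt5a_rate: float = 0.012  # WNT5A secretion per Treg per hour


@dataclass
class LymphRules:
    """Lymph-node compartment: DC cycle, clonal expansion, infiltration."""

    dc_per_antigen: float = 0.042  # expected DCs spawned per dying PC
    dc_migration_h: float = 12.0  # travel to the node; presentation starts after
    dc_presenting_h: float = 36.0  # presenting window (dies 48 h after arrival)
    stimulation_h: float = 20.0  # antigenic stimulation before first division
    division_period_h: float = 8.0  # one generation per period during expansion
    generation_min: int = 7
    generation_max: int = 10
    clone_rate: float = 0.06  # clone activations / presenting DC / step
    stim_saturation: float = 1.4  # presenting-DC level at which activation saturates
    treg_clone_fraction: float = 0.0  # fraction of activated clones that are Treg
    initial_ln_treg: int = 300  # natural Treg pool resident in the node at t=0
    treg_homeostasis: float = 0.01  # pull of the LN Treg pool toward its set-point
    treg_il2_div: float = 0.0052  # LN Treg division prob / step ~ hill(IL2_ln)
    h_il2_ln: float = 1500.0  # IL2_ln scale (proportional to activated LN CTL count)
    memory_div: float = 0.0008  # post-expansion maintenance proliferation / step
    ln_death: float = 0.006  # effector death prob / step in the node
    ln_niche: float = 6000.0  # pool size at which crowding doubles node death
    infiltration_rate: float = 0.0005  # fraction of the LN effector pool leaving / step
    treg_infiltration_rate: float = 0.0017  # Tregs home to the tumour at their own rate
    infiltration_cap: int = 6  # max cells relocated / step
    il10_dc_suppress: float = 0.95  # IL10 impairs DC activation by up to this fraction
    il10_exclusion: float = 0.9  # IL10-rich tumours exclude CTL entry by up to this fraction
    h_il10_exclusion: float = 600.0  # half-saturation (total IL10 stock) of CTL exclusion
    h_il10_dc: float = 120.0  # half-saturation (total tumour IL10 stock) of the DC effect


@dataclass
class AngioRules:
    """Endothelial sprout dynamics."""

    onset_diameter_mm: float = 2.0
    n_sprouts: int = 8
    sprout_mean_frac: float = 0.50  # normal profile along the parent vessel
    sprout_sd_frac: float = 0.12
    sprout_exclusion_frac: float = 0.14  # no seeds in the first/last 14% of the vessel
    p_move: float = 0.105  # tip step attempt prob / 2 h (EC proliferation-limited)
    grad_weight: float = 120.0  # lambda: gradient term weight in the tip score
    noise: float = 0.15  # stochastic term scale
    branch_age_h: float = 18.0
    branch_coef: float = 0.004  # p_branch = min(1, coef * VEGF_local)
    branch_basal: float = 0.0
    vegf_consumption: float = 0.05  # VEGF units consumed per tip per hour


@dataclass
class AndrogenConfig:
    blood_floor: float = 0.10
    tissue_floor: float = 0.20
    relax_tau_h: float = 48.0
    crpc_synthesis_rate: float = 3.2e-6  # tissue units / resistant cell / h
    crpc_plateau: float = 0.65


@dataclass
class FieldConfig:
    diffusion: float = 0.06  # site^2 / h (one stable substep per 2-h step)
    decay: float = 0.05  # 1/h


@dataclass
class EventTimeline:
    """Scheduled biological events (hours from simulation start)."""

    castration_h: float = 672.0  # week 4
    horizon_h: float = 1512.0  # 9 weeks
    drug_start_h: float | None = None  # defaults to castration_h

    def __post_init__(self):
        if self.castration_h > self.horizon_h:
            raise ValueError("castration must precede the horizon")
        if self.drug_start_h is not None and self.drug_start_h < self.castration_h:
            raise ValueError("drug start precedes castration")


@dataclass
class TreatmentRegimen:
    """Intervention efficacies in [0, 1]; 0 disables the agent."""

    castration: bool = True
    anti_wnt5a: float = 0.0
    csf1r_inhibitor: float = 0.0  # PLX-class CSF1R blockade
    anti_il2: float = 0.0
    egfr_inhibitor: float = 0.0

    def __post_init__(self):
        for name in ("anti_wnt5a", "csf1r_inhibitor", "anti_il2", "egfr_inhibitor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} efficacy must lie in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Complete parameterisation of one simulation."""

    lattice_n: int = 50
    spacing_um: float = 150.0
    dt_h: float = 2.0
    initial_pc: int = 200
    initial_tam: int = 100
    initial_ctl: int = 2
    initial_treg: int = 2
    replicates: int = 20
    seed: int = 0
    order_salt: int = 0  # perturbs only the agent update order (for order-independence checks)
    pc: PCRules = field(default_factory=PCRules)
    tam: TAMRules = field(default_factory=TAMRules)
    ctl: CTLRules = field(default_factory=CTLRules)
    treg: TregRules = field(default_factory=TregRules)
    lymph: LymphRules = field(default_factory=LymphRules)
    angio: AngioRules = field(default_factory=AngioRules)
    androgen: AndrogenConfig = field(default_factory=AndrogenConfig)
    fields: dict = field(default_factory=lambda: {
        "wnt5a": {"diffusion": 0.06, "decay": 0.05},
        "egf": {"diffusion": 0.06, "decay": 0.05},
        "csf1": {"diffusion": 0.06, "decay": 0.05},
        "vegf": {"diffusion": 0.30, "decay": 0.002},
        "il10": {"diffusion": 0.15, "decay": 0.01},
        "il2": {"diffusion": 0.06, "decay": 0.05},
        "trail": {"diffusion": 0.15, "decay": 0.005},
    })
    ode: dict = field(default_factory=lambda: ODEParams().as_dict())
    timeline: EventTimeline = field(default_factory=EventTimeline)
    regimen: TreatmentRegimen = field(default_factory=TreatmentRegimen)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kwargs = dict(data)
        for name, sub in (
            ("pc", PCRules), ("tam", TAMRules), ("ctl", CTLRules),
            ("treg", TregRules), ("lymph", LymphRules), ("angio", AngioRules),
            ("androgen", AndrogenConfig), ("timeline", EventTimeline),
            ("regimen", TreatmentRegimen),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- dotted-path access (used by sensitivity scans and sweeps) -----
    def get_param(self, path: str):
        obj = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p) if not isinstance(obj, dict) else obj[p]
        return getattr(obj, parts[-1]) if not isinstance(obj, dict) else obj[parts[-1]]

    def set_param(self, path: str, value) -> None:
        obj = self
        parts = path.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p) if not isinstance(obj, dict) else obj[p]
        if isinstance(obj, dict):
            obj[parts[-1]] = value
        else:
            setattr(obj, parts[-1], value)

    def copy(self) -> "SimulationConfig":
        return SimulationConfig.from_dict(self.to_dict())


#: The 34 key rate parameters scanned in the default sensitivity analysis.
#: The first two are the basal proliferation rates of the androgen-dependent
#: and androgen-independent pathways in tumour cells.
KEY_PARAMETERS: tuple[str, ...] = (
    "pc.p_base_ad",
    "pc.p_base_ai",
    "pc.p_die_base",
    "pc.p_die_castrate",
    "pc.p_migrate",
    "pc.h_androgen",
    "pc.switch_rate",
    "pc.csf1_rate",
    "pc.csf1_induction",
    "pc.trail_rate",
    "pc.vegf_rate",
    "pc.w_ref",
    "pc.e_ref",
    "tam.p_die",
    "tam.div_coef",
    "tam.h_csf1",
    "tam.rec_coef",
    "tam.egf_rate",
    "tam.il10_rate",
    "tam.il10_coef",
    "tam.vegf_rate",
    "tam.wnt5a_rate",
    "ctl.p_die",
    "ctl.p_kill",
    "ctl.il10_suppress",
    "ctl.il2_rate",
    "treg.p_die",
    "treg.div_trail",
    "treg.div_il2",
    "treg.suppress_prob",
    "lymph.dc_per_antigen",
    "lymph.clone_rate",
    "lymph.infiltration_rate",
    "androgen.crpc_synthesis_rate",
)
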