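# Methods

`crpcsim` simulates the progression of prostate cancer to castration
resistance (CRPC) inside an explicitly modelled immune microenvironment,
and predicts the effect of combining androgen deprivation with targeted
agents. It is a hybrid multiscale model: a stochastic agent-based model
(ABM) on a 3D lattice for cells and tissue-scale fields, coupled to a
deterministic ODE model of intracellular signaling in tumour cells.

## Intracellular scale: the androgen-independent signaling cascade

Tumour-cell proliferation is driven by two routes. The androgen-dependent
route is a Hill function of the tissue androgen level `A`,
`p_AD = p_base_AD * A/(h_A + A)`. The androgen-independent route is a
five-species ODE cascade activated by extracellular WNT5A and EGF
(normalised doses in [0, 1]):

    ERK'  = k1 H(W; H1)  - d1 ERK
    Skp2' = k2 H(E; H2)  - d2 Skp2
    AKT'  = k3 H(Skp2; H3) - d3 AKT
    AR'   = (1-D1) k4 H(ERK; H4) + (1-D2) k5 H(AKT; H5) - d4 AR
    Prol' = k6 H(AR; H6) - d5 Prol

with `H(x; h) = x/(h + x)` and constant branch-inhibition fractions D1
(WNT5A route) and D2 (EGF route). The output coupled into the ABM is the
fold change of `Prol` relative to an unstimulated cell; because the
unstimulated steady state is zero, a fixed basal proliferation offset
(default 0.01) is added to numerator and denominator. Cells start from a
fully inactive cascade.

Two facts make the coupling cheap and robust. First, with constant
ligands every species has a closed-form steady state obtained by
composing the cascade, which the integrator (LSODA, rtol 1e-8,
atol 1e-10) is tested against. Second, the shipped rate constants place
all decay times below ten minutes, so the cascade settles well within one
simulated hour; the agent layer therefore evaluates the steady-state fold
change directly (vectorised over cells) instead of solving an initial
value problem per cell per step. The shipped constants make the WNT5A
branch the dominant AR input and the EGF branch a smaller modulator
(`k5/k4 = 0.16`), which is what produces a modest, not catastrophic,
response to EGFR blockade.

Rate constants are estimated from normalised protein time courses (pERK,
Skp2, pAKT, AR under single-ligand stimulation at 0/30/60/420 min; Skp2
only at 30 and 60 min, where it differs from control) by minimising the
L1 misfit with a real-coded genetic algorithm: tournament selection (size
3), BLX-0.5 crossover, Gaussian mutation, one elite, bounds k,d in
[1e-4, 1] 1/min and H in [1e-3, 10], followed by a deterministic
Nelder–Mead polish of the GA optimum (a standard memetic refinement; the
recorded best-objective trace stays non-increasing through it). One
parameter vector is fitted jointly to both stimulation conditions. The package ships a synthetic-
observation generator (model prediction plus clipped Gaussian noise) for
fixtures and recovery tests; recovery is asserted on the observed
trajectories (5% RMS), not on the parameters, which are not identifiable
from eight-point designs.

## Cellular scale: agents and their rules

Five cell types live on a cubic lattice (default 50^3, 150 µm sites) with
hard volume exclusion. All decisions are probability thresholds per
2-hour step resolved against counter-based dice (below).

* **Tumour cells (PC)** divide with probability
  `clamp(p_AD + p_AI, 0, 1) * (1 - N/K) * vessel_bonus`, where `p_AI =
  p_base_AI * fold(W_local, E_local)` applies only to resistant cells,
  `K` is a nutrient-limited logistic capacity and the bonus applies
  within 5 sites of a perfused vessel. Division needs an empty site at
  Chebyshev radius 1; migration searches radius 2. Sensitive cells die
  faster as androgen falls; after castration they switch one-way to the
  resistant state with a probability that ramps up over the first week
  (AR reactivation; the resistant clone dominates a castrated cohort
  after about two weeks), and resistant cells synthesise DHT, which
  raises tissue androgen toward a configurable plateau. PCs secrete
  CSF1 — induced several-fold by the systemic (blood) androgen drop, so
  the induction persists after intratumoural DHT synthesis resumes —
  plus TRAIL (mainly the resistant state) and VEGF.
* **Macrophages (TAM)** are a fast-turnover population (half-life ~1.4
  days): recruitment and division are Hill functions of local CSF1, and
  a CSF1R inhibitor scales both by (1 - efficacy). Androgen deprivation
  polarises them to an M2-like phenotype, scaling IL10 and VEGF output
  by `1 + coef*(1 - A/A0)`; they also secrete EGF and some WNT5A.
* **Cytotoxic T cells (CTL)** chase tumour-cell density, kill one
  adjacent tumour cell per step with probability reduced by local IL10
  and blocked while Treg-arrested, and secrete IL-2.
* **Regulatory T cells (Treg)** chase CTLs, arrest or (rarely) kill CTLs
  within radius 2, divide in response to local TRAIL and IL-2, and
  secrete WNT5A — closing the tumour-Treg feedback loop.

Spatial moves score candidate empty sites by `1/|d| * 1/(1+n_occupied)`
times optional per-type attraction, sample one proportionally and accept
with probability min(score, 1). The engine batch-vectorises this rule
and resolves conflicts in a dice-shuffled order.

## The lymph-node compartment

The node is well mixed. Dying tumour cells release antigen; dendritic
cells take it up, migrate for 12 h, and can stimulate naive T cells from
12 h after maturation until they die 48 h after uptake. A stimulated
clone waits 20 h, then doubles every 8 h to a target generation drawn
uniformly from {7..10} (exactly 2^g effectors), after which it joins the
effector pool, which persists by low-rate memory proliferation and
trickles into the tumour at a rate-limited random draw, entering at
empty sites beside tumour cells. Four suppressive couplings shape the
response: activation is niche-limited (saturating in presenting-DC
number); tumour IL10 impairs DC antigen processing; the node pool is
capped by a crowding term on effector death; and an IL10-rich tumour
excludes incoming CTLs (infiltration scaled down with the tumour IL10
stock — immune exclusion; Tregs are not excluded). The first three damp
the response, and exclusion is what turns the curve over: the tumour
CTL census peaks ~2.5 weeks after castration and declines by 5 weeks
even as the CRPC tumour — and with it the antigen supply — regrows. The
node also carries a natural Treg pool held near a homeostatic
set-point, expanded by IL-2 from activated CD8 cells; IL-2
neutralisation removes exactly that term, leaving the pool at its
set-point.

## Tissue scale: fields, androgen, angiogenesis

Each cytokine (WNT5A, EGF, CSF1, VEGF, IL10, IL2, TRAIL) is a
concentration field updated by per-site secretion, explicit 7-point
finite-difference diffusion with zero-flux boundaries (automatically
substepped to respect D*dt <= 1/6), first-order decay and clipped
consumption. Units are arbitrary; diffusion/decay pairs are calibration
knobs that set each species' effective range — short for contact-like
signals, long for VEGF (a far-reaching chemoattractant) and
intermediate-persistent for IL10 and TRAIL. Androgen is two well-mixed
scalars (blood, tissue) relaxing after castration toward 10% and 20% of
baseline with a 2-day time constant.

Angiogenesis starts once the tumour's effective diameter reaches 2 mm
(95th-percentile radius of tumour cells; one-way flag). Sprouts seed on
a parent vessel along one face with a truncated-normal density that
vanishes in the outer 14% of its length; tips climb the VEGF gradient at
an EC-proliferation-limited rate (~1 site/day), never revisit their own
path, may branch after an 18-h tip age with probability proportional to
local VEGF, and fuse (and go inactive) on touching another sprout's
path. With the defaults, the network reaches the tumour 10–21 days after
onset. Perfusion feeds back on growth through the vessel-proximity
bonus; the logistic capacity stands in for the vascular nutrient ceiling.

## Randomness, determinism and sensitivity

Every per-agent decision consumes a uniform variate computed as a
splitmix64 hash of `(stream seed, step, decision channel, agent id)`
rather than a draw from a shared sequential stream. Runs are therefore
bit-reproducible from `(config, seed)`, replicates use independent
derived seeds, and — crucially — two runs differing in one rate
parameter reuse identical variates for every decision common to both
(common random numbers). A zero-size perturbation reproduces a run
exactly, and ±5% scans are meaningful at small replicate counts.
Population-level draws (Poisson recruitment, lymph-node binomials) go
through keyed inverse-CDF sampling: each call site maps to a fixed
uniform per (seed, step), so between two perturbed runs a count shifts
only as far as its distribution shifts instead of desynchronising a
stream; purely positional choices use per-step generators derived from
the replicate seed.

The default sensitivity scan perturbs 34 key rate parameters by +5%
(same seeds) and reports the % change of the mean tumour burden five
weeks after castration. Because the rebound approaches the logistic
capacity by that time and perturbed runs share dice, the scan is stable;
the two basal proliferation rates are its most influential entries.

## Scale of the shipped configuration

The defaults are a desk-scale calibration: 50^3 lattice, 200 tumour
cells / 100 macrophages / 2+2 T cells at seeding, castration at week 4,
a 9-week horizon, and 20 replicates for summary statistics. Cell counts
(thousands, not the ~10^6 of a 4-mm tumour) and physical lengths are
therefore not simultaneously to scale; the calibration targets are the
*fold changes* of populations and secretion totals, which is also how
the reference observations are reported. Runs at this scale take a few
seconds each, so full replicate sets and scans complete in minutes.

## What the synthetic data do and do not show

The observation generator for the signaling fit emulates the design of
normalised immunoblot time courses: correct time points, [0, 1] scale,
additive Gaussian noise, zero-clipping. It does not emulate blot-to-blot
normalisation artefacts, loading-control error correlation, or the
ambiguity of mapping band intensity to activity, so a passing recovery
test shows the estimator works on the stated error model, not that real
blots identify the cascade. Likewise, the ABM calibration reproduces
published population fold changes; passing does not validate cell-level
spatial structure against histology, which no shipped data constrain.

## Numerical and design choices

* Explicit FTCS diffusion with a numba-compiled kernel (pure-numpy
  fallback); conservation is exact up to float64 round-off without decay.
* Fold-change reductions use the recorded census at the castration step
  as the pre-castration reference; sample SD uses n-1; replicates with a
  zero reference are excluded and counted.
* Drug efficacies default to 1.0 (complete blockade); dose-response is
  out of scope.
* The lymph node is non-spatial: no lymph-node op in the model depends on
  position, and a well-mixed pool removes an entire class of lattice
  artefacts at this scale.
* Ties and conflicts in placement are resolved sequentially in an order
  shuffled by a dedicated dice channel; an `order_salt` knob perturbs
  only that order, and summary distributions are statistically
  indistinguishable across salts.
* Known limitations: no oxygen/nutrient field (the capacity term and
  vessel bonus stand in), no vessel flow or pruning, no MHC/TCR detail,
  no pharmacokinetics, and TRAIL acts only on Treg proliferation.
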