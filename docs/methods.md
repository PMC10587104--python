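# Methods

`xpdt` couples five compartments on a 2-D tissue lattice: chemical
transport, cellular dynamics, sprouting angiogenesis, microvascular
blood flow with structural adaptation, and a two-component treatment
model of X-ray induced photodynamic therapy (X-PDT). This note records
the model equations as implemented, the closures adopted where the
underlying model family leaves choices open, the calibration of the
gap-filled constants, and what the synthetic scenarios do and do not
establish.

## Lattice and clocks

The domain is a 5 mm x 5 mm tissue patch discretized as a 200 x 200
lattice with 25 µm spacing (one cell diameter); each site holds at most
one cell. The cellular clock advances in 1 h steps, so the reported
durations 41.6 days and 141.6 days are exactly 1000 and 3400 steps.
Chemical kinetics at the tabulated dimensional rates equilibrate within
seconds, far below anything the cellular clock can resolve; each CA step
therefore advances the chemical fields by an effective chemical time
`chem_seconds_per_step` (default 0.2 s). This single coupling constant
sets how fast oxygen depletion fronts, acid plumes and capillary supply
halos develop relative to cell-cycle time, and it was calibrated once
(see Calibration) so that the avascular phase lasts the reported ~42
days. A pure quasi-steady treatment of oxygen is *not* used because it
has no solution without vascular sources: the reported behavior of the
non-vascularized scenarios (oxygen retained in proportion to the
background level at treatment time) requires the field to keep a memory
of its initial condition.

## Chemical transport

Oxygen, glucose and hydrogen ion obey

    dC_i/dt = D_i lap(C_i) + A_i + B_i

with cellular uptake `A_i = (W_i phi) * activity` and vascular exchange
`B_i = sum 2 q_i / R (C_b,i - C_w,i)` over perfused capillary segments
at a node, under no-flux boundaries. The wall concentration `C_w` is
identified with the local extravascular concentration. Intravascular
concentrations are constant. Two physiological closures matter:

* **Oxygen partition.** The tabulated blood oxygen content
  (5.6e-5 mol/L) is dominated by hemoglobin-bound oxygen; transmural
  equilibrium is set by the free plasma fraction. The exchange term
  therefore drives tissue toward `C_b,O2 * O2_partition` with the
  partition fixed so that perivascular tissue equilibrates at the
  reference tissue oxygenation 5.2e-6 mol/L. Without this, tissue near
  any capillary saturates at ten times the physiological level.
* **Arteriole wall.** The pre-existing parent vessel is an arteriole;
  its thick wall exchanges essentially no solute
  (`parent_exchange_fraction = 0`). Oxygen enters the tissue only
  through the capillary network formed by angiogenesis, which is why
  perfusion begins only after the first loops anastomose.

Glucose and acid additionally relax toward their baseline
concentrations at first-order rates `lambda_G`, `lambda_H`
(host-tissue homeostasis: systemic glucose supply and proton
buffering/venous clearance). Without these, a closed no-flux domain
containing a centimeter-scale glycolytic tumor acidifies and
glucose-starves globally within weeks, contrary to the late-time tissue
state the model family reports. No such relaxation is applied to
oxygen: limited oxygen delivery is the central premise of the model.

Numerics: each step applies the exact pointwise solution of the
linearized reaction (Michaelis-Menten uptake linearized about the
current field, which preserves positivity) followed by the exact
semigroup of the discrete 5-point Neumann Laplacian evaluated in a
cosine basis. The diffusion substep conserves mass to rounding. The
angiogenesis morphogens and VEGF, whose sources evolve on the cellular
clock, are kept at quasi-steady profiles via a factorized sparse solve
of the same discretization; the steady solver is cross-checked against
a dense solve in the tests.

## Metabolism and the cellular automaton

Per-cell demand rates follow Michaelis-Menten oxygen consumption with a
glycolytic pathway that defends ATP production when oxygen is scarce
(Warburg multiplier `P_G`, default 1) and excretes protons in
proportion to the glycolytic flux; the baseline ATP rate is
`A_0 = (29/5) V_O2`. Classification uses the *demand* rates achievable
at the local concentrations: a cell dies when its normalized ATP rate
falls below `A_d = 0.3` or the local pH falls below its acid tolerance
(tumor cells resist to pH 6); it rests when the ATP rate sits in
[0.3, 0.8) or, for tumor cells, when local oxygen falls below the
hypoxia threshold (`hypoxia_fraction * 5.2e-6 mol/L`), which also
raises the VEGF-secretion flag; otherwise it proliferates through a
24 h G1/S/G2/M cycle (11/8/4/1 h) and divides into an empty von-Neumann
neighbor on completing mitosis. Normal cells divide only when their
Moore-neighborhood occupancy falls below 80% and cycle an order of
magnitude more slowly than tumor cells (host tissue turnover).

The transport sink uses activity-scaled rates: proliferative tumor
cells consume at the full tabulated rates; dormant tumor cells throttle
their oxidative pathway to `quiescent_metabolic_fraction` while their
glycolytic pathway continues at full strength — hypoxia-arrested tumor
cells keep fermenting, which is what acidifies the margin. Host tissue
runs at a low homeostatic baseline (`normal_metabolic_fraction`)
regardless of division state; this constant sets how fast the initial
oxygen reservoir decays over the simulated weeks.

Acid-mediated invasion supplies the space for growth: dead normal cells
lyse and free their sites (dead tumor cells persist as necrotic
material). Normal-cell acid tolerance is heterogeneous, drawn once per
site from a clipped normal distribution (mean pH 7.25, s.d. 0.08). The
heterogeneity is load-bearing: the acid plume of the initial 9-cell
seed is only ~0.2 pH units deep, and it is the sensitive tail of the
tolerance distribution that clears the first margin sites and lets
invasion bootstrap reproducibly across seeds.

## Angiogenesis

Sprout initiation on the parent vessel follows an adaptive
sprout-spacing scheme: a node sprouts when the quasi-steady activator
(sourced by hypoxic tumor cells) reaches `A_trigg` while the local
inhibitor is at or below threshold. Candidate nodes are scanned in
descending activator order and each new sprout immediately deposits a
steady inhibitor plume whose threshold contour sits at a radius drawn
uniformly from 6-16 lattice units, which both spaces sprouts
irregularly and caps the initial wave at about eight sprouts along the
200-node parent vessel. Deposition persists while the sprout exists
(an expiry knob exists for studying successive sprouting waves but is
off by default).

Tip migration is hybrid discrete-continuum: the endothelial flux
(diffusion `D_e`, VEGF chemotaxis `chi/(1+sigma c)`, fibronectin
haptotaxis `rho`) is discretized on the five-point stencil and the
stencil coefficients, clamped and normalized, are the movement
probabilities of each discrete tip (the canonical nondimensional
coefficient values are used; the stencil step `tip_dt` is expressed on
the unit square, so coarse test grids rescale it). Tips are
self-avoiding, cannot re-enter the parent vessel, lay down a 2 µm
capillary segment per move, update fibronectin locally, and age.
A tip older than `psi_ref * psi_multiplier` (18 h reference) splits
with per-step probability `branch_prob`, but only where normalized VEGF
is high (`vegf_branch_threshold`): sprouts cross host tissue as single
trunks and arborize around their hypoxic target, which concentrates the
capillary mesh — and later the singlet-oxygen kill — inside the tumor.
Contact with existing vasculature fuses (anastomosis) with probability
`fuse_prob`, closing a loop and retiring the tip; tips boxed in for
longer than `tip_stall_limit` steps regress. Only loops that connect
two distinct parent-vessel junctions carry flow, so perfusion — and
hence oxygen delivery — switches on abruptly as cross-trunk
anastomoses close.

## Hemodynamics

Poiseuille conductances `g = pi R^4 / (8 mu_app L)` with the empirical
in-vitro apparent-viscosity law `mu_app(R, H_D)` (characteristic
minimum near 7 µm diameter; plasma viscosity 1.2 cP at zero
hematocrit; discharge hematocrit fixed at 0.45) enter a nodal
mass-conservation solve with Dirichlet pressures at the parent inlet
and outlet (100 mmHg end-to-end). Dead-end branches carry zero flow.
Radii then adapt by `dR = S_total R dt` with
`S_total = S_wss + S_p + S_m - k_s`: a wall-shear stimulus
`log10(tau_w + tau_ref)`, a pressure stimulus `-k_p log10 tau_e(P)`
using the standard sigmoidal shear-vs-pressure curve, a metabolic
stimulus `k_m log10(Q_ref/(Q H_D) + 1)` that rescues low-flow
segments, and a constant intrinsic shrinking tendency `k_s`. The
shrinking term is retained even though the source text lists exactly
three stimuli: without it every perfused segment has strictly positive
total stimulus and all radii run to the clamp, destroying the reported
contrast between young (thin) and old (thick) vessels. Stimuli are
smoothed over two evaluations (the look-ahead predictor), radii are
clamped to [1, 14] µm, and the `2q/R` exchange density is rebuilt from
the updated radii each step, so thinner vessels are more efficient
oxygen sources per unit wall area.

## Treatment

The PDT component converts dose to scintillation photon density,

    N_scint = d * 1e-3 * 6.2e12 * C_sc * (mu/rho ratio) * Y_sc,

throttles it pointwise by the molecular-oxygen saturation
`C/(C + Kp/Kot)` (one photon assumed per singlet-oxygen molecule), and
multiplies by the cell volume `V_cell = 1/phi` to get the per-cell
yield. A compensation coefficient `eta_c` is inverse-engineered once so
the reference plan (4 Gy, 4 mg/ml, reference oxygen) reaches the
lethal threshold `N_th = 4e7` molecules/cell exactly (`eta_c ~ 663`);
it stands in for the non-optical energy-transfer channels the yield
chain omits. Cells die with probability
`min(1, eta_c N_1O2 / N_th)`; a one-hit alternative
`1 - exp(-eta_c N_1O2 / N_th)` is available by configuration. Normal
tissue sees half the drug concentration by default.

The RT + radiosensitizer component applies
`SF = exp[-(1 + bC)(alpha d + beta d^2)]` per cell, with the tumor
alpha modulated by cycle phase for proliferative cells
(G1/S/G2/M multipliers 0.8/0.9/1.25/1.25 — G2 and mitosis most
sensitive; beta is phase-independent) and normal tissue using its own
alpha/beta = 3.1 pair. At 4 Gy the beta term dominates the exponent,
which is why the RT kill fraction is nearly independent of the tumor's
phase composition.

`apply_xpdt` runs the PDT kill first and the survival law on the
survivors; the mechanisms are independent, so combined survival is the
product and the order is statistical bookkeeping only. Treated tumor
cells are terminal; treated normal cells revert to their prior state
after a 4.16-day repair delay. Oxygen enhancement of the RT component
(OER) is deliberately not modeled: the source material asserts it only
qualitatively. Background-oxygen scenarios (0.125x-10x reference) are
applied as treatment-time rescalings of the oxygen field and
intravascular level on the same grown geometry.

## Calibration of gap-filled constants

The tabulated physiology fixes the metabolic, transport and treatment
constants. The constants the model family leaves to citation —
morphogen kinetics, `A_trigg`, inhibitor spacing, tip/branching rates,
adaptation constants, the chemical time coupling, the resting-activity
scales and the host acid tolerance — were calibrated once against the
reported reference scenario and then frozen as defaults:

* `chem_seconds_per_step`, `normal_metabolic_fraction` and the acid
  tolerance distribution reproduce the avascular endpoint (~3.2e3
  cells, ~70% quiescent at 41.6 days) and leave the far-field
  oxygen at roughly one tenth of the reference level by 141.6 days,
  which is what the reported normal-tissue kill fraction implies.
* `A_trigg` is set so the first sprouting wave occurs as the avascular
  phase ends (~day 42), and the inhibitor decay length and radius
  range cap that wave at ~8 sprouts.
* `q_i`, `branch_prob`, `fuse_prob` and the VEGF branching gate set
  how much of the tumor the perfused mesh covers at treatment time,
  and through it the singlet-oxygen kill fractions.

Calibration used the defaults' own scenario (no other data), and no
constant is adjusted at run time.

## What the scenarios do and do not show

The synthetic scenarios emulate the reference experiment: a 9-cell
seed in 80%-dense host tissue, one parent arteriole, growth to the
avascular plateau, angiogenesis to a perfused network, and a single
treatment at 141.6 days. They do not emulate real-tissue features such
as three-dimensional diffusion, red-cell phase separation, pulsatile
flow, interstitial pressure, immune involvement or photosensitizer
pharmacokinetics; passing tests show internal consistency with the
model family's reported behavior, not predictive validity for tissue.

Known limitations worth stating plainly:

* The singlet-oxygen kill fraction is delivery-limited and
  self-limiting: oxygen halos inside the tumor re-awaken dormant cells,
  which consume the halo back to the hypoxia boundary. The reported
  per-compartment split (quiescent cells killed eight times more often
  than proliferative ones) is not reproduced — here kills concentrate
  in the perivascular, partly proliferative cuffs.
* Under the independent-mechanism rule, combined X-PDT viability is
  bounded below by (1 - PDT kill) x RT survival. With the reported
  component values (22.73% and 37.26%) that bound is ~48%, well above
  the reported combined viabilities (33.5%/35.08%), which therefore
  include a synergy the source does not specify. The bound, not the
  reported number, is what this implementation can reach.
* Degenerate inputs: zero-dose or zero-concentration plans are exact
  no-ops of the PDT chain; anoxic nodes have exactly zero yield; flow
  solves on networks without boundary anchoring raise a topology error
  rather than returning a singular solution.
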