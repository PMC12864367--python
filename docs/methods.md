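# Methods

## The model

`pembrosim` simulates the immune response of locally advanced MSI-H/dMMR
colorectal cancer to neoadjuvant pembrolizumab (anti-PD-1) with a minimal
mechanistic model spanning two well-mixed compartments: the tumour site (TS,
volume `V_TS`) and the tumour-draining lymph node (TDLN, volume `V_LN`).

The full formulation tracks 32 dynamic states: viable and necrotic cancer
cells; immature/mature dendritic cells in the TS and mature DCs in the TDLN;
naive, effector and exhausted CD8+ T cells; naive and effector regulatory
T cells; naive and M2 macrophages; resting and activated NK cells; six
cytokines (IL-2, IFN-γ, TNF, TGF-β, IL-10, IL-12); and the checkpoint/drug
species — unbound PD-1 on CD8s and NK cells, unbound PD-L1,
PD-1/pembrolizumab complexes, and free drug, in both compartments. Kinetic
conventions are uniform: activation and lysis by cytokines follow
Michaelis–Menten saturation `λ X_i X_j/(K + X_j)`, inhibition enters as a
divisor `1/(1 + X_j/K)`, cell–cell lysis and production are mass action,
and every species decays linearly. Tumour growth is logistic with carrying
capacity `C_0`. T-cell expansion in the TDLN is a deterministic division
program: `n_max` divisions with first-cycle time `Δ⁰` and later cycle time
`Δ` give a burst of `2^{n_max}` attenuated by the in-program death factor
`exp(−d τ)`, with `τ = Δ⁰ + (n_max − 1)Δ`. Cross-compartment fluxes carry
volume ratios `V_TS/V_LN` (DC migration to the TDLN) or `V_LN/V_TS`
(effector T-cell egress to the TS) and transit-survival factors
`exp(−d τ_migration)`.

The PD-1/PD-L1 complexes are never integrated. Their dissociation rate
(1.44 s⁻¹, mean lifetime below one second) is orders of magnitude faster
than everything else, so each complex is closed algebraically,
`Q = (λ_on/λ_off) · P_D · P_L`, and appears only inside inhibition divisors
of cytotoxicity and T-cell activation. Because a single on/off ratio is
shared by all PD-1-bearing cells and both compartments, the baseline state
must satisfy cross-consistency relations (`Q^{T8}(0)·P_D^K(0) =
Q^K(0)·P_D^{T8}(0)`, and the TDLN complex is predicted by the TS ratio);
`pembrosim.verify` checks these to the printing precision of the baseline
tables (1%).

## QSSA reduction

Twelve species relax much faster than the cell populations: the six
cytokines, the effector CD8 and Treg pools in the TDLN (removal =
egress + death), naive macrophages (removal = polarisation + death) and the
three PD-1/drug complexes (removal = dissociation + internalisation). Each
is replaced by the closed form obtained by zeroing its balance, leaving 20
slow states. Drug binding then acts through a lumped net rate
`μ = λ_bind · d_int/(λ_off + d_int)`: complexes that dissociate return both
drug and receptor, so only internalisation is a net sink. TGF-β production
in the closure uses viable cancer cells and M2 macrophages — the same
sources as the dynamic balance (one variant spelling found with an effector-
Treg source was treated as a slip; the dynamic and nondimensional balances
agree on C + M2).

Reduced-model runs report fast species from their closed forms; their
initial values therefore differ from the tabulated fast initial conditions
unless those lie on the slow manifold. This is the expected transient
discrepancy of any QSSA, and the trajectory-closeness test accounts for it
by initialising the full model on the slow manifold before comparing.

## Dosing

Infusions are intravenous boluses: each dose of ξ mg raises free drug in
*both* compartments by `ξ · f_pembro` (molec/cm³) instantaneously — the
same linear dose-to-concentration factor is applied at the TS and the TDLN.
Impulses never pass through the adaptive stepper: the driver integrates
piecewise between dose times, applies the jump exactly at each `t_j`
(doses at t = 0 before the first step), and restarts. The default regimen
is 200 mg every 21 days for 6 cycles (2.5 mg/kg for an 80 kg patient),
over an 18-week horizon.

## Numerical integration

`integrate` uses scipy's adaptive low-order explicit Runge–Kutta pair
(`RK23`) with rtol 1e-6 / atol 1e-9 and dense output, so the save grid is
decoupled from solver steps. The vector field is evaluated on states
clipped to the non-negative orthant; the orthant is forward invariant for
the exact flow (every loss term carries its own species), so clipping only
guards sub-tolerance undershoot by the stepper. Any scipy method name can
be passed for stiff configurations (`LSODA`, `Radau`); the packaged default
parameter set is mild enough for the explicit pair.

## Agent-based analogue

The nondimensionalisation assigns each species a group size `g_X`
(`X = g_X · X̃`); the substitution is exact for any positive `g`, and
`rescale_params` implements the full tilde/hat parameter table. The
standard recipe anchors group sizes to the baseline state: one agent is
1/5000 of the initial viable-cancer population, 1/2000 of most cell
species, 1/1000 of checkpoint pools and of a reference drug bolus
(3×10¹⁴ molec/cm³ ≈ one 200 mg dose), with `g = 1` for the algebraically
closed fast species. The ensemble state is the integer whole-compartment
count `n_X = X · V_comp / g_X` (per-agent concentration `γ_X = g_X/V_comp`),
so a run starts from exactly those 5000/2000/1000 counts; compartment
volumes cancel inside a compartment and reappear as the printed
`V_TS/V_LN` factors on migration fluxes.

Updates are time-driven and synchronous on a Δt = 0.01 day grid (the
default; dose times are snapped to the nearest grid point, error ≤ Δt/2).
A rate λ becomes a per-step probability `1 − exp(−λΔt)`. Design choices
that matter:

* **Competing risks per agent.** All loss and transition hazards acting on
  one species are summed; removal occurs with the total-hazard probability
  and the realised cause is drawn categorically (multinomial over the
  removed agents). This cannot remove an agent twice in one step and agrees
  with independent per-event Bernoulli trials to O(Δt).
* **Binomial aggregation.** Agents of a species are exchangeable, so
  per-agent trials collapse into one binomial (and one multinomial) draw
  per species per step — statistically identical and orders of magnitude
  faster than per-agent loops.
* **Floor-plus-Bernoulli spawning.** Sources and transition bursts with
  fractional means m spawn `⌊m⌋ + Bernoulli(frac(m))` agents, so every
  spawn has exactly its target expectation (e.g. one cancer-agent necrosis
  event spawns `g_C/g_{N_c}` necrotic agents in expectation).
* **Births are not competing risks.** Proliferation leaves the parent in
  place, so birth trials are drawn separately from removal trials; a net
  negative logistic term (above carrying capacity) is handled as an extra
  death hazard.
* **Shared rate decomposition.** The ABM consumes the same per-capita
  source/birth/loss/transition decomposition that assembles the reduced
  vector field, making the mean field exact by construction: the expected
  one-step increment (available in closed form via
  `expected_step_increment`) equals the forward-Euler increment of the
  reduced ODE to O(Δt²).
* **Reproducibility.** One root seed; replicate streams are spawned with
  `numpy.random.SeedSequence(seed).spawn(n_reps)`. Identical inputs give
  bit-identical trajectories.

## The packaged default parameter set (synthetic)

The defaults in `_data/default_params_synthetic.yaml` are a synthetic
calibration, not measured values. They were fixed, once, to satisfy:

* the printed baseline state is self-consistent — checkpoint and cytokine
  synthesis/decay balances reproduce the tabulated initial concentrations
  given the tabulated cell densities, and `λ_on/λ_off = 2.13×10⁻¹⁶
  cm³/molec` matches the tabulated complex/receptor/ligand ratios in both
  compartments, with `λ_off = 1.44 s⁻¹`;
* the timescale separation the QSSA assumes (fast species ≥ ~10× faster
  than slow ones; the complex closure ~10⁵× faster);
* the qualitative study conditions: without treatment the tumour persists
  near carrying capacity; under the standard regimen checkpoint blockade
  triggers CTL expansion and NK disinhibition and drives a deep (~99%)
  response that leaves residual disease rather than deterministic
  extinction, so stochastic replicates can diverge.

Two deliberate departures from physical kinetics are documented here. The
drug–receptor association constant is slowed (free-PD-1 half-life ≈ 25 min
after a bolus instead of seconds) so the explicit low-order solver remains
practical; target engagement still completes within hours of each infusion,
far below the cell-dynamics timescale, which is what the downstream model
sees. And TGF-β production is M2-dominated, so immunosuppression relaxes
only partially as the tumour regresses — this keeps the late kill/growth
balance marginal, the regime in which inter-replicate variability is
pronounced. Patient-to-patient realism of individual rate constants is out
of scope; conclusions supported by the test suite are about the *simulator*
(consistency of the three formulations, convergence, reproducibility), not
about clinical quantities.

## Problem sizes and verification scope

Deterministic runs integrate 126 days (18 weeks). Stochastic checks use
10 replicates at Δt = 0.01 day for the treated heterogeneity ensemble
(~10⁴ agents in play), 5 replicates for mean-field comparison, and a few
hundred replicates of order-10² agent linear toys for the analytic oracles
(closed-form exponential decay/growth means within 3 standard errors,
Δt-refinement stability, one-step expectation vs Euler). The across-
replicate heterogeneity statistic is the relative range
`(max − min)/min` of final total cancer concentration `V = C + N_c`;
"variation" has no standard operational definition, so the choice is
flagged wherever the number is reported. V includes necrotic cells by
default (`total_cancer(..., include_necrotic=False)` reports viable only).

## Known limitations

* No spatial structure, chemotaxis or diffusion; both compartments are
  well mixed.
* The ABM is a discrete-time tau-leaping-style scheme, not an exact
  (Gillespie) simulation; fidelity is first order in Δt.
* Memory CD8s, CD4+ T cells, M1 macrophages (beyond their drain on naive
  macrophages), TDLN cytokines, additional anatomical compartments and
  T-cell avidity are outside the model's scope.
* Parameter values are synthetic (above); no uncertainty quantification or
  re-estimation is attempted.
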