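# Methods

`coshnet` models steady-state oxygen transport by red blood cells (RBCs)
through capillary networks of the cerebral cortex, with the goal of
quantifying capillary outflow saturation heterogeneity (COSH) — the
flow-weighted standard deviation of hemoglobin saturation at the distal ends
of capillary paths — and the degree to which diffusive oxygen exchange
through tissue ("diffusive interaction") suppresses it. This note records
the models, the parameter choices, the numerical design, and what the
synthetic studies do and do not establish.

Units throughout: lengths μm, time s, pressure mmHg, oxygen amounts μm³ O₂
at standard conditions (so solubilities are numerically the familiar
mL O₂ · mL⁻¹ · mmHg⁻¹ values).

## Network model

A capillary network is a graph of vessels (edges) with 3-D polyline
centerlines, uniform per-vessel diameter, and nodes that are either interior
junctions (degree ≥ 2) or boundary stubs (degree 1). Following common
practice for two-photon reconstructions, diameters are affinely rescaled to
a target mean ± SD (default 5 ± 1.5 μm) with a hard floor of 3 μm, and three
radii are derived per vessel: plasma radius r_p = d/2, RBC radius
r_c = 0.8 r_p with the RBC diameter clamped to [3, 8] μm, and outer
endothelium radius r_w = 1.25 r_p. Per-vessel flow state comprises the
volumetric flow q, RBC velocity v_rbc = q/(π r_p²) (no Fåhræus distinction
between bulk and RBC velocity, so tube and discharge hematocrit coincide),
tube hematocrit H_T, linear density μ_LD = H_T (r_p/r_c)² (the fraction of
vessel length occupied by the RBC column), and RBC volume flux q_rbc.

## Blood flow and reconstruction from sparse velocimetry

Flow is pressure-driven Poiseuille flow with the Pries–Secomb in-vivo
apparent viscosity law (plasma viscosity 1.2 mPa·s). Hematocrit is
propagated in topological order through the flow-directed graph: at
two-branch diverging junctions the empirical phase-separation law splits the
RBC flux, elsewhere the split is proportional to blood flow; converging
junctions mix conservatively. Because viscosity depends on hematocrit, the
pressure solve and the hematocrit redistribution are iterated to a fixed
point; the iteration is damped (relaxation 0.3 on the hematocrit field used
in the resistances, tightened in later phases) because the discontinuous
phase-separation law otherwise sustains period-2 limit cycles. Nodal volume
and RBC-flux conservation hold to machine precision at every iterate by
construction.

Real studies measure RBC speeds in only a subset of vessels. The boundary
pressures (the unknowns of the problem) are therefore reconstructed by
minimizing dissipated hydraulic power plus a weighted speed misfit,

J(p_B) = Σ_e q_e² R_e + λ Σ_m w_m (|v_m| − v̂_m)²,

subject to a minimum mean pressure drop between inflow-labelled and
outflow-labelled boundaries (this inequality is what prevents the trivial
zero-flow minimum when no measurements are supplied). Weights default to
w_m = 1/v̂_m² because line-scan velocimetry errors scale with speed and the
misfit would otherwise ignore slow vessels. λ is set by a discrepancy
principle when the measurement noise level is known (the misfit at its noise
floor balances the initial power, so the power term keeps regularizing
unmeasured vessels); for noise-free measurements λ is set large
(10⁶ × power/misfit at the initial guess), which is the exact-recovery
regime.

Because only speeds enter the misfit, the optimization is non-convex in the
velocity sign pattern, and the hematocrit–viscosity feedback makes it worse:
a sign pattern can be self-consistently wrong (it looks optimal under the
hematocrit field it itself produces). The solver therefore proceeds in
phases: (A) a multistart search over boundary-pressure perturbations under
uniform inflow hematocrit generates candidate sign patterns, each refined by
alternating quadratic solves with single-vessel, worst-residual-pair and
residual-connected-component sign flips; (B) every distinct candidate is
scored by the measurement misfit it reaches after a frozen-sign
self-consistent hematocrit loop (a quick pass for all, a long pass for the
best few); (C) residual-guided single flips are evaluated with fresh
self-consistent loops, including flips of the slowest measured vessels,
whose speeds match under either sign and whose directions are therefore the
weakly determined ones; (D) a full-tolerance polish, run both with the best
pattern frozen and with free sign refinement, keeping the better fit. With
complete noise-free measurements this recovers reference velocity fields to
well under 1% relative RMS per vessel; with sparse noisy measurements the
result is a regularized estimate, not a truth claim. The outer loops use
iteration caps of a few hundred; the coupled fixed point converges
geometrically but slowly under the damping that the phase-separation law
requires.

## Hemoglobin saturation transport (reduced model)

Within a vessel the saturation S of the flowing RBC phase obeys the
advection balance Q_O2(S) dS/dx = −j_t, where

Q_O2(S) = v_rbc (μ_LD π r_c² C0 + π r_p² α_eff dP_eq/dS)

is the convective oxygen carrying capacity — hemoglobin-bound oxygen plus
plasma-dissolved oxygen advected at equilibrium with the RBCs — and
j_t = M0 π (r_t² − r_w²) is the tissue extraction per unit vessel length of
an equivalent Krogh cylinder of radius r_t consuming at the constant
volumetric rate M0. Axial diffusion is neglected. The hemoglobin equilibrium
is the Hill curve S_eq(P) = Pⁿ/(Pⁿ + P50ⁿ), with the inverse P_eq(S) and its
closed-form slope used throughout; S is clipped to [10⁻⁹, 1 − 10⁻⁹] inside
slope evaluations to avoid the singular endpoints without affecting results
at the 10⁻⁸ level. Saturation is floored at 0: a fully desaturated RBC stops
supplying tissue, and the flooring is reported rather than redistributed.

Heterogeneity is carried as a discrete distribution of saturation "atoms"
(S, w) per vessel. At a converging bifurcation the child inherits the union
of the parents' distal atoms weighted by the parents' RBC-flux shares; at a
diverging bifurcation children inherit the parent distribution unchanged.
Cascades of convergences grow distributions combinatorially, so the atom
count is capped at 32 per vessel by merging the two closest-S atoms
(mass-conserving weighted mean, which preserves the first moment exactly and
the second approximately). This propagation contains no within-vessel
exchange between atoms — no RBC diffusive interaction — which is precisely
why comparing it against the particle model isolates that mechanism. Each
atom is integrated with adaptive Runge–Kutta (rtol 10⁻⁸, atol 10⁻¹⁰, dense
output at 50 points per vessel).

## Tissue territories

Geometric territories partition the tissue box (network bounding box plus a
5 μm margin) by nearest centerline, on a regular voxel grid with 1 μm
default spacing; centerlines are sampled at half the voxel spacing and
queried through a KD-tree, which approximates exact point-to-segment
distance to a small fraction of the spacing. Functional territories invert
the transport model: for a vessel with observed proximal and distal
saturations, the tissue radius r_t is bisected (bracket [r_w, 200 μm],
tolerance 10⁻⁶ in S) so that the forward integration reproduces the drop.
Volumes and equivalent radii interconvert through V = L π (r_t² − r_w²).

At steady state the two volume sums must agree because total consumption is
M0 × total volume; the conservation report quantifies the relative
discrepancy on the vessels where both are defined. Three accounting choices
keep that comparison faithful to the simulation it summarizes. First, the
fit uses the RBC flux realized in the particle window (transit count × RBC
volume / window) rather than the nominal flow-solution flux — the hard-core
injection constraint makes the realized flux fall slightly short of
nominal. Second, the distal saturation entering the fit is inverted from
the flux-exact oxygen the vessel released during the window (per-transit
entry/exit bookkeeping attributes whole transits to the window and carries
an edge bias). Third, a vessel with net negative release — an
oxygen-uptaking capillary, which arises when neighbouring territories
over-supply its tissue — contributes its signed functional volume
(release/(M0 × window)) directly; the equivalent radius is undefined there
and the vessel is excluded from radius statistics but not from the volume
balance. Vessels whose fit is flagged (no transits, saturation floored,
bracket exceeded) are excluded from both sums and listed.

## Particle surrogate for the moving-RBC model

The full 3-D finite-volume moving-RBC computational model is replaced by a
desk-scale particle surrogate designed to retain the two mechanisms under
study. Individual RBCs (volume 49 μm³, cylindrical with the vessel's r_c)
advect at the vessel RBC velocity; at diverging junctions each RBC is routed
by a Bernoulli draw with the phase-separation flux fractions, producing
natural hematocrit fluctuations; injection at functional inflow vessels is a
gamma renewal process with mean spacing l_rbc/(μ_LD v_rbc) and a
coefficient of variation of 0.5 by default, with a hard-core constraint
preventing overlap.

Tissue is lumped into per-vessel axial bins (5 μm default width, widened
where an RBC would cross more than one bin per step) whose volumes come from
the geometric territories, floored at a 1 μm perivascular shell so bin
capacitance never degenerates. Each RBC exchanges with its current bin
through a conductance per unit length 1/K_loc, with K_loc = K_IV plus the
Krogh-annulus wall-to-mean-tissue term (log(r_t/r_w) − ½)/(2π D_t α_t);
the bin integrates RBC fluxes, constant consumption, and diffusive coupling
to the nearest bin of each neighboring vessel. Two vessels are coupled when
their centerlines approach within the sum of their equivalent tissue radii
(abutting territories); the pair conductance is chosen so that the series
resistance between the two RBC streams approaches K_CI,i + K_CI,j, the
value implied by the closed-form capillary-interaction model, and each
bin's total coupling is shared across its partner vessels so the aggregate
interaction matches the closed form once rather than once per neighbour —
an internal consistency calibration, verified directly in a
two-parallel-vessel experiment where the surrogate damps the inter-vessel
saturation difference exponentially at ~0.8× the closed-form rate. Tissue tension updates are
explicit Euler at dt = 1 ms with stability caps on the exchange and
coupling conductances (binding only for pathologically small bins); tissue
tension is floored at 0 with the consumption shortfall logged. The per-RBC
oxygen capacity is V_rbc C0 plus the RBC's share of plasma-dissolved oxygen
(column length l_rbc/μ_LD), which makes the uniform-spacing limit converge
to the saturation ODE including its plasma term.

Runs last 10 s with statistics over the final 2 s; the tissue field is
warm-started from the reduced-model saturation estimates, which shortens the
(α_t P/M0 ≈ 2.6 s) tissue turnover transient well below the 8 s burn-in. An
oxygen budget (release = consumption − shortfall + storage change) closes to
well under 1% and is reported with every run.

## Closed-form interaction predictions

The paired-capillary saturation difference ΔS and the within-vessel
saturation SD σ_S both follow Q_O2(S̄) dh/dx = −(h/K) dP_eq/dS|_S̄ alongside
the mean balance, with K = K_CI (capillary interaction, K_CI = K_IV +
(log(r_t,mean/r_w) − ½)/(2π D_t α_t)) or K = K_RI (RBC interaction). With
frozen coefficients the solution is an exact exponential, used as the
analytic oracle; by default coefficients follow the evolving mean. A
log-linear least-squares fit extracts decay rates from simulated profiles.

## The synthetic study and its scope

The reference datasets behind the published network statistics are not
deposited, so the package generates its own study conditions:

* Topology: ~0.87 n junctions placed uniformly at random in the target
  bounding box, candidate vessels from the 3-D Delaunay triangulation,
  greedily pruned (longest edges and highest endpoint-degree sums first,
  connectivity preserved) to exactly n vessels, after carving ~0.24 n
  boundary stubs near the top and bottom faces. This reproduces the
  degree-3-dominated mesh character, the broad junction-spacing
  distribution and the converging-bifurcation counts of cortical capillary
  networks with few parameters; for n ≤ 6 a star is produced instead.
  Boundary stubs in the upper half of the box are labelled inflow, the rest
  outflow.
* Geometry: diameters are drawn from a moment-matched truncated normal
  (floor 3 μm). Vessel arc lengths reproduce the target truncated-normal
  length moments exactly: sampled lengths are rank-matched to the edge
  chords, an affine map of the targets is found by nested bisection so that
  the chord-clipped lengths hit the target mean and SD (a vessel cannot be
  shorter than its chord), and each centerline is bent by a two-harmonic
  transverse bump whose amplitude is bisected to the exact arc length.
* Reference flow: boundary pressures are drawn with ±25% heterogeneity and
  calibrated to the target mean speed; among five draws the one with the
  fewest near-stagnant vessels is kept (imaged capillary networks are fully
  perfused; stagnant vessels here are artifacts of random boundary
  pressures). The speed distribution is then shaped toward the published
  mean ± SD by rank-matching truncated-normal target speeds to the
  provisional field and realizing them with the package's own
  reconstruction machinery — the network's cycle constraints leave a
  natural residual spread.
* Measurements: a 40% random vessel subset with Gaussian speed noise of
  SD 0.05 mm/s emulates line-scan coverage.

The analysis pipeline then treats the generated study exactly like real
data: reconstruct flow from the sparse measurements, partition territories,
propagate the saturation ODE with geometric and with functional radii, run
the particle surrogate, and compare. Vessels whose expected transit count
over the averaging window is below 5 (plus any left without an upstream
supply) are removed from all three transport models alike — the analog of
restricting the oxygen simulation to a well-perfused subnetwork — because
they cannot yield saturation statistics yet would otherwise consume tissue
oxygen that the volume comparison cannot attribute.

What passing synthetic tests do show: internal consistency of the solvers
(conservation at machine precision, oracle equivalences between the
particle model, the ODE model and the closed forms), and that the
qualitative physics of diffusive interaction — damping proportional to
heterogeneity, fluctuation-driven growth at low heterogeneity, functional
territories adapting to flow rather than anatomy — emerges at realistic
parameter values. What they do not show: agreement with any specific real
network, since the generator reproduces only low-order statistics (no
penetrating vessels, layers, or measured adjacency), and the particle
surrogate replaces the resolved 3-D oxygen field with lumped compartments.

## Default parameters

| Parameter | Value | Meaning |
| --- | --- | --- |
| C0 | 0.5 | RBC oxygen binding capacity, μm³ O₂/μm³ RBC |
| P50, n | 47.9 mmHg, 2.64 | Hill curve (mouse blood) |
| α_eff | 3.3 × 10⁻⁵ | effective capillary solubility, μm³ O₂ μm⁻³ mmHg⁻¹ |
| α_t | 3.89 × 10⁻⁵ | tissue solubility |
| D_t | 2400 μm²/s | tissue oxygen diffusivity |
| M0 | 6 × 10⁻⁴ μm³ O₂ μm⁻³ s⁻¹ | consumption (≈1.6 μmol cm⁻³ min⁻¹, anesthetized cortex) |
| K_IV | 0.7 mmHg·s/μm² | intravascular transport resistance per unit length |
| K_RI | 2.5 mmHg·s/μm² | RBC-interaction coefficient |
| V_rbc | 49 μm³ | RBC volume (mouse MCV) |
| inflow H_T | 0.25 | tube hematocrit at functional inflows |
| inflow S | 0.6 constant, or U(0.5, 0.7) per inflow vessel | boundary saturation |
| dt, t_end, window | 1 ms, 10 s, last 2 s | particle run schedule |

All are configuration values; conclusions drawn from the test suite are
designed to be invariant to the exact K coefficients (ratios, monotonicity,
ordering), since their authoritative values belong to a companion
intravascular-transport analysis and are not re-derived here.

## Known limitations

* The particle surrogate's tissue is per-vessel and axially lumped: no
  resolved radial gradients, no region-dependent diffusivity/solubility,
  no true 3-D functional territories.
* The reconstruction's sign search is heuristic; with sparse noisy
  measurements different locally optimal flow fields can fit equally well,
  and no uncertainty is propagated to the oxygen stages.
* The generator matches printed low-order statistics only; realized speed
  SD can exceed the target because network structure resists shaping.
* Per-vessel properties are uniform along a vessel; mid-vessel converging
  inflows and intravascular saturation gradients are not represented.
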