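# Methods

## Problem

EmrE, a small multidrug-resistance efflux pump of *E. coli*, works as an
antiparallel asymmetric homodimer whose two chains occupy inward-open and
outward-open conformations; the two subunits give separate NMR resonance sets
(monomer A and monomer B). In the wild-type homodimer the two assignments are
populated 50/50 by symmetry. Introducing a single point mutation into one
chain — a *minimal heterodimer* — breaks the degeneracy: the labeled
wild-type chain partitions between the A and B positions with populations
p_A and p_B that report the conformational bias induced by the mutation.
This package (i) estimates p_A/p_B, the equilibrium constant K and the bias
free energy from peak-intensity tables of a reference homodimer sample and a
mixed labeled/unlabeled sample, and (ii) propagates a measured bias through a
kinetic alternating-access model to predict its effect on proton-driven drug
transport.

## Population estimator

A mixed sample at molar labeled fraction x = labeled/(labeled + unlabeled)
forms, under random pairing, dimers in proportions x² (labeled homodimer),
2x(1−x) (labeled/unlabeled heterodimer) and (1−x)² (NMR-invisible unlabeled
homodimer). Counting per visible monomer position — a doubly labeled
homodimer contributes one chain to the A resonance and one to the B resonance
— the visible signal splits as

    f_homo = x / (2 − x),    f_het = 2(1 − x) / (2 − x),

so 1:3 mixing gives f_homo = 1/7, f_het = 6/7. A Monte-Carlo pairing
simulation of a finite chain pool is kept in the test suite as an independent
check of this counting rule. Observed intensities are

    I_A,obs = I_A (f_homo + f_het p_A),
    I_B,obs = I_B (f_homo + f_het p_B),    p_A + p_B = 1,

with I_A, I_B the intrinsic per-residue intensities from the homodimer
reference (the two resonance sets are not exactly equal in intensity, so the
mixed-sample ratio is normalized by the reference ratio). With
R = (I_A,obs/I_B,obs)/(I_A/I_B) the closed-form inverse is

    p_A = (R − f_homo) / (f_het (1 + R)),

exact for R in [f_homo, 1/f_homo]; outside that window no population in
[0, 1] explains the data. By default an out-of-range residue raises an error
naming it; with `clamp_out_of_range` the estimate is pinned to the nearer
bound, the appropriate behavior when intensity noise pushes a residue
slightly past the identifiable window.

Aggregation averages per-residue p_A arithmetically over the residues paired
(both A and B peaks present) in *both* tables — by default requiring at least
3, with the canonical reporter set being the seven isoleucines I11, I54, I58,
I62, I68, I88, I101 — then converts: K = p_B/p_A and ΔG = R T ln K with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T defaulting to 298 K (solution spectra at
25 °C; configurable). Averaging on the population scale rather than the
free-energy scale keeps a single noisy residue from dominating through the
logarithm. The reported population range is mean ± 1 sample SD (ddof = 1,
n = 7 is a small sample), clipped to [0, 1]. The experimental report the
estimator emulates quotes an asymmetric range (90–99% about 96%), which a
symmetric ±SD rule cannot produce exactly; the multiplier/transformation
behind that printed range is not recoverable, so the ±1 SD convention is used
and stated in every report.

## Synthetic data

No peak lists are deposited for these experiments, so `dimerbias.synthetic`
generates them under the estimator's own signal model plus realism the model
does not assume:

- intrinsic A/B ratios drawn per residue from U[0.7, 1.4] (reference peaks
  differ residue to residue);
- multiplicative Gaussian noise (1 + ε, ε ~ N(0, cv²)) independently on every
  peak height, default cv = 0.05 — a typical height uncertainty for
  well-resolved methyl peaks; peak-height noise is multiplicative to first
  order;
- an optional detection floor that silently drops weak peaks, standing in for
  homodimer-baseline peaks lost near the contour cutoff;
- one `numpy.random.default_rng` seed controlling everything, so identical
  seeds give byte-identical CSV output.

What the generator does *not* emulate: lineshapes, chemical-shift overlap,
relaxation differences between A and B sites, and intermediate-exchange
broadening (the regime where a weakly binding drug makes intensities
unquantifiable — quantification in that regime is out of scope). Passing
recovery tests therefore show the inversion and its noise response are
correct under the stated signal model, not that real spectra meet that
model's assumptions.

Calibration under the defaults (200 seeds, 7 residues, cv = 0.05, true
p_B = 0.96): the mean recovered p_B stays within 0.02 of truth and the
seed-to-seed SD of the 7-residue mean stays under 0.03, with per-sample SD
windows of a few percent — the same order as the experimentally printed
90–99% spread, i.e. that spread is plausible as plain intensity noise.

## Transport model

Ten states: species E, EH, EH2 (zero/one/two protons on the glutamate pair,
supporting 1:1 or 2:1 H⁺:drug coupling), ES and EHS (drug bound), each
inward- or outward-facing. Per face, binding steps E↔EH, EH↔EH2 (proton) and
E↔ES, EH↔EHS (substrate); a conformational flip for every species. Binding
uses the ligand concentration on the open face; pH is clamped on both faces
(buffered), exterior substrate is clamped, interior substrate evolves with
the net flux through the inward-facing substrate steps scaled by
n_transporters/(N_A·V).

Default rates are plausible rather than fitted (the published fitted set
behind the original simulation is not reproduced here, so the transport
predictions are directional, not numeric): proton on-rates 10¹⁰ M⁻¹s⁻¹ with
both protonation steps at pKa 7, substrate k_on 10⁷ M⁻¹s⁻¹ with Kd 1 µM,
50 s⁻¹ symmetric flips, a 200 nm-diameter vesicle (4.19×10⁻¹⁸ L) with 10
transporters, boundary pH_in 6.5 / pH_out 8.0 and 5 µM exterior substrate —
an inwardly acidic vesicle whose proton gradient drives drug uptake. Every
constant is overridable through the YAML/JSON config.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e−8, atol 1e−12
on occupancies and 1e−14 on concentration); runs start from the stationary
distribution at the initial interior concentration (null space of the rate
matrix) so initial rates carry no relaxation transient. The initial rate is
the least-squares slope of S_in over the first 5% of the span. Occupancy
conservation is exact in the generator (columns sum to zero); the integrator
is required to hold it to 1e−8 and trajectories are renormalized on output.
Degenerate inputs (disconnected state graphs, zero-rate edges that would make
the null space multidimensional) raise configuration or numerical errors
rather than returning garbage.

### Cycle audit

For every independent cycle of the state graph (networkx cycle basis) the
auditor compares ln(∏ forward / ∏ reverse) — binding steps pseudo-first-order
at face concentrations — with the driving force detailed balance demands from
the cycle's net ligand translocation (one proton moved across one pH unit
contributes ln 10). The mismatch is accumulated concentration-free (intrinsic
k_on/k_off and flip terms only), which is algebraically identical but stays
finite when a compartment starts empty; |mismatch| > 1e−6 flags the rate set
as thermodynamically inconsistent.

### Conformational bias

A measured heterodimer population enters as a per-species energy tilt:
species s is stabilized by RT·ln α_s in the favored conformation, with the
flip equilibrium shifting by α_s² (α = √(p_major/p_minor) reproduces the
measured skew on a symmetric baseline). Rates follow the geometric-mean
(φ = ½) split of the endpoint energy shifts: flips become α·k_io, k_oi/α —
preserving the intrinsic flip timescale k_io·k_oi — and, when α differs
between species (drug binding attenuates the bias; default attenuation
exponent ½, with 0 confining the bias to drug-free states), the same-face
binding steps between those species acquire the compensating
√(α_from/α_to) factor. That compensation is not optional physics: cycle
closure forces the two heterodimer orientations to differ in binding
affinity once free and bound states are biased unequally, and it is what
keeps every closed-cycle balance exactly unchanged — bias redistributes
kinetics without injecting energy, which the auditor verifies for any bias
spec. A flips-only mode (`compensate_binding=False`) exists for comparison;
the auditor flags the inconsistency any unequal-α spec then introduces.

A consequence worth stating: under the consistent tilt, stabilizing the
*inward*-open empty carrier strengthens substrate binding on the outward
face and loosens it on the inward face, so the inward-open-favoring
heterodimer loads, releases and transports faster than its mirror image
(~1.1× initial rate at the 96/4 skew under the default rates), and beats the
mirror at every tested skew (2, 5, 24). The effect is *not* monotone in the
skew itself — extreme bias in either direction traps the carrier on one
face, as alternating access requires flips both ways — so the directional
signature is pairwise dominance over the mirror topology, not monotone
growth. The experimentally reported ~5.6× between opposite insertion
topologies depends on the original fitted rate constants and is therefore a
directional, not numeric, comparison here.

## Problem sizes

Test and acceptance runs use 7-residue tables, 200-seed noise calibrations,
and uptake simulations of 5–50 s with 50–200 output points on the ten-state
model — sizes at which every check completes in seconds while leaving the
estimator and integrator in their production configuration.

## Known limitations

- Peak heights stand in for volumes; no lineshape or exchange-broadening
  modelling, so intermediate-exchange conditions are out of quantitative
  scope.
- Uncertainty is the ±1 SD rule only; no bootstrap or Bayesian posterior.
- The two-state (A/B) model is built in; more than two conformers per chain
  are not representable.
- The transport model has no membrane potential term, no stochastic engine,
  and unfitted default rates; interior pH is clamped (buffered vesicle), so
  proton-leak effects on the gradient are not modelled.
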