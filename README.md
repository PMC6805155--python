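# dimerbias

Quantifying conformational bias in minimal heterodimers of an
alternating-access transporter, and predicting what that bias does to
transport.

The small multidrug efflux pump EmrE is an antiparallel, asymmetric
homodimer: its two chains occupy inward-open and outward-open conformations
and give two resolvable NMR resonance sets (monomers A and B). Pairing a
labeled wild-type chain with an unlabeled single-point mutant — a *minimal
heterodimer* — breaks the 50/50 symmetry, and the labeled chain's partition
between the A and B positions measures the bias the mutation induces. This
package is for NMR spectroscopists and transporter modelers who have peak
intensities from such mixed samples and want populations, equilibrium
constants, free energies, and kinetic consequences.

## Model

A mixed sample at labeled molar fraction x forms labeled homodimers and
labeled/unlabeled heterodimers; among NMR-visible monomer positions

    f_homo = x/(2−x),   f_het = 2(1−x)/(2−x)        (1:3 mixing → 1/7, 6/7).

Observed intensities combine the homodimer baseline with the
population-weighted heterodimer term,

    I_A,obs = I_A (f_homo + f_het p_A),   I_B,obs = I_B (f_homo + f_het p_B),

with p_A + p_B = 1 and I_A, I_B the intrinsic intensities from a pure
homodimer reference. With R = (I_A,obs/I_B,obs)/(I_A/I_B) the estimator
inverts in closed form,

    p_A = (R − f_homo) / (f_het (1 + R)),

averages over the paired reporter residues, and reports
K = p_B/p_A and ΔG = RT ln K (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, T = 298 K by
default). A synthetic-data module generates reference/mixed table pairs
under this same signal model (per-residue intrinsic ratios, multiplicative
intensity noise, truth sidecar) so the whole pipeline is testable without
experimental downloads.

A second component turns a measured bias into transport predictions: a
ten-state alternating-access kinetic model (E/EH/EH2/ES/EHS on each membrane
face) with a vesicle-uptake ODE simulator, a null-space steady-state oracle,
and a thermodynamic cycle auditor. The bias enters as a per-species energy
tilt that shifts flip equilibria by α² while keeping every closed reaction
cycle thermodynamically balanced. See `docs/methods.md` for the full model
and its assumptions.

## Worked example

Generate a synthetic apo-like sample (true p_B = 0.96, 5% intensity noise)
and estimate the populations back:

```
$ dimerbias simulate-peaks --pa 0.04 --seed 7 --noise-cv 0.05 -o apo
reference: apo_ref.csv
mixed: apo_mixed.csv
truth: apo_truth.json

$ dimerbias estimate --mixed apo_mixed.csv --reference apo_ref.csv \
      --labeled 1 --unlabeled 3 --clamp -o apo_report.json
pB = 0.9621 (range 0.9486-0.9755), K = 25.37, dG = 1.915 kcal/mol over 7 residues
```

The estimate recovers the ground truth within the noise: the labeled chain
spends ~96% of its time in the monomer-B conformation, an equilibrium
constant near 24 and a mutation-induced bias free energy near 1.9 kcal/mol.
`apo_report.json` holds the per-residue populations and the ±1 SD range;
every run also writes a manifest (parameters, seed, version) next to its
output.

The mixing statistics and the transport comparison are one-liners:

```
$ dimerbias mix-fractions --labeled 1 --unlabeled 3
x = 0.25
f_homo = 0.142857
f_het = 0.857143

$ dimerbias compare --pb 0.96 --bound-exponent 0 --t-end 10 --out cmp.json
rate ratio = 1.101, final ratio = 1.087
```

`compare` simulates pH-driven drug uptake into a vesicle for the two mirror
insertion topologies of a heterodimer with a 96/4 conformational skew on its
drug-free states: the inward-open-favoring topology transports ~1.1× faster
and accumulates more drug under the default rate set. `check-cycles` audits
any model configuration for detailed-balance consistency, and `transport`
writes full occupancy/concentration trajectories.

## Library use

```python
from dimerbias import (mixing_fractions, estimate_population,
                       read_peak_table, build_model, bias_from_populations,
                       compare_heterodimers)

fr = mixing_fractions(1, 3)                    # f_homo = 1/7, f_het = 6/7
mixed = read_peak_table("apo_mixed.csv", sample_kind="mixed")
ref = read_peak_table("apo_ref.csv", sample_kind="reference_homodimer")
est = estimate_population(mixed, ref, fr)      # est.p_B_mean, est.K, est.delta_G

model = build_model()                          # or build_model("model.yaml")
bias = bias_from_populations(est.p_B_mean, toward="in", bound_exponent=0)
rate_ratio, final_ratio = compare_heterodimers(model, bias, bias.mirrored(),
                                               t_end=10.0)
```

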