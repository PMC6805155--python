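"""Statistical dimer-mixing model and the two-state population estimator.

A mixed sample of isotopically labeled wild-type and unlabeled mutant chains
forms, under random pairing at molar labeled fraction x, dimers in proportions
x^2 (labeled homodimer), 2x(1-x) (labeled/unlabeled heterodimer) and (1-x)^2
(invisible unlabeled homodimer).  Among NMR-visible dimers, counting one
labeled monomer in each resonance position per labeled homodimer gives

    f_homo = x / (2 - x),      f_het = 2(1 - x) / (2 - x).

Observed mixed-sample intensities are then a homodimer baseline plus the
heterodimer term weighted by the conformer population of the labeled chain:

    I_A,obs = I_A * (f_homo + f_het * p_A)
    I_B,obs = I_B * (f_homo + f_het * p_B),     p_A + p_B = 1,

where I_A, I_B are the residue's intrinsic intensities from a pure homodimer
reference (the A/B peaks of a reference spectrum are not exactly equal).
Defining the doubly-normalized ratio R = (I_A,obs / I_B,obs) / (I_A / I_B),
the unique algebraic inverse is

    p_A = (R - f_homo) / (f_het * (1 + R)),

identifiable exactly for R in [f_homo, 1/f_homo].  The conformer equilibrium
constant is K = p_B / p_A and the bias free energy is dG = R_gas*T*ln(K).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from .errors import (
    DegenerateModelError,
    EstimationError,
    InconsistentIntensityError,
    InsufficientDataError,
    ValidationError,
)
from .peaks import PeakTable, PopulationEstimate

__all__ = [
    "R_GAS",
    "MixingFractions",
    "EstimatorConfig",
    "mixing_fractions",
    "per_residue_population",
    "estimate_population",
    "equilibrium_constant",
    "bias_free_energy",
]

#: Gas constant in kcal mol^-1 K^-1.
R_GAS = 1.987e-3


@dataclass(frozen=True)
class MixingFractions:
    """Homodimer/heterodimer fractions among labeled-signal-containing dimers.

    ``labeled_fraction`` is x = labeled / (labeled + unlabeled) (molar).
    Fractions are per visible monomer position: a doubly-labeled homodimer
    contributes one labeled chain to each of the A and B resonances.
    """

    labeled_fraction: float
    f_homo: float
    f_het: float

    def __post_init__(self) -> None:
        if not 0.0 < self.labeled_fraction <= 1.0:
            raise ValidationError("labeled_fraction must be in (0, 1]")
        if not (0.0 <= self.f_homo <= 1.0 and 0.0 <= self.f_het <= 1.0):
            raise ValidationError("f_homo and f_het must lie in [0, 1]")
        if abs(self.f_homo + self.f_het - 1.0) > 1e-12:
            raise ValidationError("f_homo + f_het must equal 1")


@dataclass(frozen=True)
class EstimatorConfig:
    temperature: float = 298.0  # K, for the free-energy conversion
    clamp_out_of_range: bool = False
    min_paired_residues: int = 3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.min_paired_residues < 1:
            raise ValidationError("min_paired_residues must be >= 1")


def mixing_fractions(labeled: float, unlabeled: float) -> MixingFractions:
    """Dimer fractions from the molar amounts mixed.

    At a 1:3 labeled:unlabeled ratio this gives f_homo = 1/7, f_het = 6/7.
    """
    if labeled <= 0:
        raise ValidationError("labeled amount must be positive")
    if unlabeled < 0:
        raise ValidationError("unlabeled amount must be non-negative")
    x = labeled / (labeled + unlabeled)
    return MixingFractions(
        labeled_fraction=x,
        f_homo=x / (2.0 - x),
        f_het=2.0 * (1.0 - x) / (2.0 - x),
    )


def per_residue_population(
    I_A_obs: float,
    I_B_obs: float,
    I_A_ref: float,
    I_B_ref: float,
    fractions: MixingFractions,
    clamp: bool = False,
    residue_label: str = "",
) -> float:
    """Invert one residue's intensities to the monomer-A population p_A.

    R outside [f_homo, 1/f_homo] cannot arise from any population in [0, 1];
    with ``clamp`` the result is pinned to the nearer bound (noise can push R
    slightly past the identifiable window), otherwise it is an error.
    """
    for name, v in (
        ("I_A_obs", I_A_obs),
        ("I_B_obs", I_B_obs),
        ("I_A_ref", I_A_ref),
        ("I_B_ref", I_B_ref),
    ):
        if v <= 0:
            raise ValidationError(f"{name} must be positive, got {v!r}")
    if fractions.f_het == 0:
        raise DegenerateModelError(
            "f_het = 0: a pure homodimer sample carries no population information"
        )
    R = (I_A_obs / I_B_obs) / (I_A_ref / I_B_ref)
    p_A = (R - fractions.f_homo) / (fractions.f_het * (1.0 + R))
    if p_A < 0.0 or p_A > 1.0:
        if clamp:
            return min(1.0, max(0.0, p_A))
        where = f" for residue {residue_label}" if residue_label else ""
        raise InconsistentIntensityError(
            f"intensity ratio R = {R:.6g}{where} lies outside the identifiable "
            f"window [{fractions.f_homo:.6g}, {1.0 / fractions.f_homo:.6g}]; "
            "pass clamp=True to pin to the nearer bound"
        )
    return p_A


def equilibrium_constant(p_A: float) -> float:
    """Conformer equilibrium constant K = p_B / p_A = (1 - p_A) / p_A."""
    if not 0.0 < p_A < 1.0:
        raise ValidationError("K is undefined for p_A at 0 or 1")
    return (1.0 - p_A) / p_A


def bias_free_energy(K: float, temperature: float = 298.0) -> float:
    """Bias free energy dG = R_gas * T * ln(K) in kcal/mol.

    Positive when the B conformer dominates (K > 1); this is the energetic
    preference induced by the single mutation in the partner chain.
    """
    if K <= 0:
        raise ValidationError("K must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return R_GAS * temperature * math.log(K)


def estimate_population(
    mixed: PeakTable,
    reference: PeakTable,
    fractions: MixingFractions,
    config: EstimatorConfig = EstimatorConfig(),
) -> PopulationEstimate:
    """Aggregate per-residue inversions into a population estimate.

    Uses residues paired (both A and B peaks) in *both* tables, inverts each,
    averages p_A arithmetically, and reports mean +/- 1 sample SD as the
    population range (clipped to [0, 1]).  Averaging happens on the population
    scale, not the free-energy scale, so a single noisy residue cannot
    dominate through the log.
    """
    if mixed.sample_kind != "mixed":
        raise ValidationError("first table must have sample_kind='mixed'")
    if reference.sample_kind != "reference_homodimer":
        raise ValidationError(
            "second table must have sample_kind='reference_homodimer'"
        )
    shared = sorted(
        set(mixed.paired_residues()) & set(reference.paired_residues()),
        key=_seq_number,
    )
    if len(shared) < config.min_paired_residues:
        raise InsufficientDataError(
            f"only {len(shared)} residue(s) paired in both tables; "
            f"need at least {config.min_paired_residues}"
        )
    per_residue: dict[str, float] = {}
    for res in shared:
        per_residue[res] = per_residue_population(
            mixed.intensity(res, "A"),
            mixed.intensity(res, "B"),
            reference.intensity(res, "A"),
            reference.intensity(res, "B"),
            fractions,
            clamp=config.clamp_out_of_range,
            residue_label=res,
        )
    p_A_values = [per_residue[r] for r in shared]
    p_A_mean = sum(p_A_values) / len(p_A_values)
    p_B_mean = 1.0 - p_A_mean
    if p_A_mean <= 0.0 or p_A_mean >= 1.0:
        raise EstimationError(
            "mean population pinned at 0 or 1 (possibly clamping artifacts); "
            "equilibrium constant undefined"
        )
    p_B_values = [1.0 - p for p in p_A_values]
    p_B_sd = statistics.stdev(p_B_values) if len(p_B_values) > 1 else 0.0
    p_B_range = (max(0.0, p_B_mean - p_B_sd), min(1.0, p_B_mean + p_B_sd))
    K = p_B_mean / p_A_mean
    return PopulationEstimate(
        per_residue=per_residue,
        p_A_mean=p_A_mean,
        p_B_mean=p_B_mean,
        p_B_sd=p_B_sd,
        p_B_range=p_B_range,
        K=K,
        delta_G=bias_free_energy(K, config.temperature),
        temperature=config.temperature,
        residues_used=list(shared),
        condition=mixed.condition,
    )


def _seq_number(label: str) -> int:
    from .peaks import residue_number

    return residue_number(label)
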