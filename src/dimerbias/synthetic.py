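"""Synthetic peak-table generator.

No peak lists are deposited with the experiments this package analyses, so
the generator emulates them under the same signal model the estimator
inverts: per-residue intrinsic A/B intensity ratios (the reference A and B
peaks are not exactly equal), the statistical homodimer baseline in the mixed
sample, and multiplicative Gaussian noise on every peak height.  It is the
ground-truth source for all pipeline tests: a noise-free pair must be
inverted exactly, and noisy pairs calibrate how much spread in the recovered
population plain intensity noise produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .mixing import mixing_fractions
from .peaks import PeakRecord, PeakTable, write_peak_table

__all__ = ["DEFAULT_RESIDUES", "SyntheticSpec", "generate_pair", "write_pair"]

#: The seven isoleucine reporter residues with well-resolved methyl signals.
DEFAULT_RESIDUES = ("I11", "I54", "I58", "I62", "I68", "I88", "I101")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic reference/mixed sample pair.

    noise_cv is the coefficient of variation of multiplicative Gaussian noise
    applied independently to every peak height; detection_floor drops peaks
    weaker than the threshold (weak homodimer-baseline peaks near the noise
    floor simply vanish from real peak lists).
    """

    p_A_true: float
    labeled: float = 1.0
    unlabeled: float = 3.0
    residues: tuple[str, ...] = DEFAULT_RESIDUES
    intrinsic_ratio_range: tuple[float, float] = (0.7, 1.4)
    noise_cv: float = 0.05
    detection_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_A_true <= 1.0:
            raise ValidationError("p_A_true must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.detection_floor < 0:
            raise ValidationError("detection_floor must be >= 0")
        lo, hi = self.intrinsic_ratio_range
        if not 0 < lo <= hi:
            raise ValidationError("intrinsic_ratio_range must be 0 < lo <= hi")
        if not self.residues:
            raise ValidationError("residues must be non-empty")


def generate_pair(spec: SyntheticSpec) -> tuple[PeakTable, PeakTable]:
    """Generate (reference, mixed) peak tables for one synthetic sample.

    Per residue the intrinsic B intensity is fixed at 1 and the intrinsic A
    intensity is drawn uniformly from ``intrinsic_ratio_range``; the mixed
    table applies the statistical mixing model at the spec's labeled:unlabeled
    ratio with the spec's ground-truth population.  Identical seeds give
    identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    fr = mixing_fractions(spec.labeled, spec.unlabeled)
    p_A, p_B = spec.p_A_true, 1.0 - spec.p_A_true

    ref_records: list[PeakRecord] = []
    mixed_records: list[PeakRecord] = []
    for res in spec.residues:
        intrinsic_A = rng.uniform(*spec.intrinsic_ratio_range)
        intrinsic_B = 1.0
        ideal = {
            "ref": {"A": intrinsic_A, "B": intrinsic_B},
            "mixed": {
                "A": intrinsic_A * (fr.f_homo + fr.f_het * p_A),
                "B": intrinsic_B * (fr.f_homo + fr.f_het * p_B),
            },
        }
        for table, records in (("ref", ref_records), ("mixed", mixed_records)):
            for monomer in ("A", "B"):
                noise = 1.0 + spec.noise_cv * rng.standard_normal()
                value = ideal[table][monomer] * noise
                if value < spec.detection_floor:
                    continue  # peak lost below the detection threshold
                records.append(
                    PeakRecord(
                        residue_label=res,
                        monomer=monomer,
                        intensity=max(value, 0.0),
                    )
                )

    condition = f"synthetic pA={spec.p_A_true} seed={spec.seed}"
    reference = PeakTable(
        sample_kind="reference_homodimer",
        records=ref_records,
        labeled_protein="wild-type",
        condition=condition,
    )
    mixed = PeakTable(
        sample_kind="mixed",
        records=mixed_records,
        labeled_protein="wild-type",
        condition=condition,
    )
    return reference, mixed


def write_pair(spec: SyntheticSpec, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>_ref.csv``, ``<prefix>_mixed.csv`` and a truth sidecar.

    The sidecar records every generator parameter so a downstream estimate can
    be compared against ground truth without re-deriving it.
    """
    prefix = Path(prefix)
    reference, mixed = generate_pair(spec)
    paths = {
        "reference": prefix.parent / f"{prefix.name}_ref.csv",
        "mixed": prefix.parent / f"{prefix.name}_mixed.csv",
        "truth": prefix.parent / f"{prefix.name}_truth.json",
    }
    write_peak_table(reference, paths["reference"])
    write_peak_table(mixed, paths["mixed"])
    truth = {
        "p_A_true": spec.p_A_true,
        "p_B_true": 1.0 - spec.p_A_true,
        "labeled": spec.labeled,
        "unlabeled": spec.unlabeled,
        "residues": list(spec.residues),
        "intrinsic_ratio_range": list(spec.intrinsic_ratio_range),
        "noise_cv": spec.noise_cv,
        "detection_floor": spec.detection_floor,
        "seed": spec.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
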