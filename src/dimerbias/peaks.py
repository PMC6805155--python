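"""Peak-intensity tables and population-estimate reports.

An asymmetric transporter dimer gives two resolvable resonance sets, one per
monomer (A and B).  Experiments yield per-residue peak intensities for a
reference homodimer sample and for a mixed labeled/unlabeled sample; the
estimator in :mod:`dimerbias.mixing` converts the two tables into
conformational populations.  This module holds the table/record types, the
CSV and Sparky-style readers, a CSV writer, and the JSON report round-trip
for estimates.

Intensities are peak heights in arbitrary spectrometer units; heights are the
standard proxy for populations when lineshapes are comparable, and no
lineshape fitting is attempted here.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "PeakRecord",
    "PeakTable",
    "PopulationEstimate",
    "read_peak_table",
    "write_peak_table",
    "write_estimate",
    "read_estimate",
    "residue_number",
]

MONOMERS = ("A", "B")

_RESIDUE_RE = re.compile(r"^[A-Za-z]+(\d+)$")


def residue_number(label: str) -> int:
    """Sequence number of a residue label like ``I58`` -> 58."""
    m = _RESIDUE_RE.match(label)
    if m is None:
        raise ValidationError(f"unparseable residue label: {label!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class PeakRecord:
    """One peak: a residue's resonance for monomer A or B.

    omega1/omega2 are optional chemical-shift coordinates (ppm); they are
    carried through for provenance but never used by the estimator.
    """

    residue_label: str
    monomer: str
    intensity: float
    omega1: float | None = None
    omega2: float | None = None

    def __post_init__(self) -> None:
        if not self.residue_label:
            raise ValidationError("residue_label must be non-empty")
        if self.monomer not in MONOMERS:
            raise ValidationError(
                f"monomer must be one of {MONOMERS}, got {self.monomer!r}"
            )
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValidationError(
                f"intensity must be finite and >= 0, got {self.intensity!r} "
                f"for {self.residue_label}{self.monomer}"
            )


@dataclass
class PeakTable:
    """All peaks of one sample (reference homodimer or mixed)."""

    sample_kind: str  # "reference_homodimer" | "mixed"
    records: list[PeakRecord] = field(default_factory=list)
    labeled_protein: str = ""
    condition: str = ""

    _KINDS = ("reference_homodimer", "mixed")

    def __post_init__(self) -> None:
        if self.sample_kind not in self._KINDS:
            raise ValidationError(
                f"sample_kind must be one of {self._KINDS}, got {self.sample_kind!r}"
            )
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.residue_label, rec.monomer)
            if key in seen:
                raise ValidationError(
                    f"duplicate assignment {rec.residue_label}{rec.monomer}"
                )
            seen.add(key)

    def intensity(self, residue_label: str, monomer: str) -> float:
        for rec in self.records:
            if rec.residue_label == residue_label and rec.monomer == monomer:
                return rec.intensity
        raise KeyError(f"no record for {residue_label}{monomer}")

    def paired_residues(self) -> list[str]:
        """Residues with both A and B records, sorted by sequence number."""
        have: dict[str, set[str]] = {}
        for rec in self.records:
            have.setdefault(rec.residue_label, set()).add(rec.monomer)
        paired = [r for r, mons in have.items() if mons == {"A", "B"}]
        return sorted(paired, key=residue_number)


@dataclass
class PopulationEstimate:
    """Aggregate two-state populations of the labeled chain in a heterodimer.

    ``per_residue`` maps residue label -> p_A.  ``K = p_B_mean / p_A_mean`` is
    the conformer equilibrium constant and ``delta_G = R*T*ln(K)`` (kcal/mol)
    the bias free energy induced by the partner's mutation.
    """

    per_residue: dict[str, float]
    p_A_mean: float
    p_B_mean: float
    p_B_sd: float
    p_B_range: tuple[float, float]
    K: float
    delta_G: float
    temperature: float
    residues_used: list[str]
    condition: str = ""

    _TOL = 1e-9

    def __post_init__(self) -> None:
        from .mixing import R_GAS  # local import to avoid a cycle

        if abs(self.p_A_mean + self.p_B_mean - 1.0) > self._TOL:
            raise ValidationError("p_A_mean + p_B_mean must equal 1")
        if self.p_B_sd < 0:
            raise ValidationError("p_B_sd must be >= 0")
        lo, hi = self.p_B_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("p_B_range must lie within [0, 1]")
        if self.K <= 0:
            raise ValidationError("K must be positive")
        if abs(self.K - self.p_B_mean / self.p_A_mean) > self._TOL * max(1.0, self.K):
            raise ValidationError("K must equal p_B_mean / p_A_mean")
        expected_dG = R_GAS * self.temperature * math.log(self.K)
        if abs(self.delta_G - expected_dG) > 1e-6:
            raise ValidationError("delta_G must equal R*T*ln(K)")


# ---------------------------------------------------------------------------
# readers / writers

_CSV_REQUIRED = ("residue", "monomer", "intensity")
_SPARKY_ASSIGNMENT_RE = re.compile(r"^([A-Za-z]+\d+)([AB])$")


def read_peak_table(
    path: str | Path,
    dialect: str = "csv",
    *,
    sample_kind: str = "mixed",
    labeled_protein: str = "",
    condition: str = "",
) -> PeakTable:
    """Read a peak table.

    The CSV dialect is normative: header ``residue,monomer,intensity`` with
    optional ``w1_ppm,w2_ppm`` columns.  The Sparky dialect is a best-effort
    convenience parser for whitespace-delimited peak lists of the form
    ``assignment w1 w2 height`` where the assignment is ``<residue><monomer>``
    (e.g. ``I58A``).
    """
    path = Path(path)
    if dialect == "csv":
        records = _read_csv_records(path)
    elif dialect == "sparky":
        records = _read_sparky_records(path)
    else:
        raise FormatError(f"unknown dialect {dialect!r} (expected 'csv' or 'sparky')")
    return PeakTable(
        sample_kind=sample_kind,
        records=records,
        labeled_protein=labeled_protein,
        condition=condition,
    )


def _read_csv_records(path: Path) -> list[PeakRecord]:
    try:
        df = pd.read_csv(path, dtype={"residue": str, "monomer": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        w1 = getattr(row, "w1_ppm", None)
        w2 = getattr(row, "w2_ppm", None)
        records.append(
            PeakRecord(
                residue_label=str(row.residue).strip(),
                monomer=str(row.monomer).strip(),
                intensity=float(row.intensity),
                omega1=None if w1 is None or pd.isna(w1) else float(w1),
                omega2=None if w2 is None or pd.isna(w2) else float(w2),
            )
        )
    return records


def _read_sparky_records(path: Path) -> list[PeakRecord]:
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected 'assignment w1 w2 height', got {line!r}"
            )
        m = _SPARKY_ASSIGNMENT_RE.match(parts[0])
        if m is None:
            raise FormatError(
                f"{path}:{lineno}: unparseable assignment {parts[0]!r} "
                "(expected e.g. I58A)"
            )
        records.append(
            PeakRecord(
                residue_label=m.group(1),
                monomer=m.group(2),
                intensity=float(parts[3]),
                omega1=float(parts[1]),
                omega2=float(parts[2]),
            )
        )
    return records


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a table in the normative CSV dialect (deterministic row order)."""
    path = Path(path)
    has_shifts = any(r.omega1 is not None for r in table.records)
    cols = ["residue", "monomer", "intensity"]
    if has_shifts:
        cols += ["w1_ppm", "w2_ppm"]
    rows = []
    for rec in sorted(
        table.records, key=lambda r: (residue_number(r.residue_label), r.monomer)
    ):
        row = {
            "residue": rec.residue_label,
            "monomer": rec.monomer,
            "intensity": repr(rec.intensity),
        }
        if has_shifts:
            row["w1_ppm"] = "" if rec.omega1 is None else repr(rec.omega1)
            row["w2_ppm"] = "" if rec.omega2 is None else repr(rec.omega2)
        rows.append(row)
    lines = [",".join(cols)]
    lines += [",".join(r[c] for c in cols) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def write_estimate(estimate: PopulationEstimate, path: str | Path) -> None:
    """Write a population estimate as a round-trippable JSON report."""
    payload = {
        "condition": estimate.condition,
        "temperature_K": estimate.temperature,
        "per_residue": dict(estimate.per_residue),
        "pA_mean": estimate.p_A_mean,
        "pB_mean": estimate.p_B_mean,
        "pB_sd": estimate.p_B_sd,
        "pB_range": list(estimate.p_B_range),
        "K": estimate.K,
        "delta_G_kcal_mol": estimate.delta_G,
        "residues_used": list(estimate.residues_used),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_estimate(path: str | Path) -> PopulationEstimate:
    data = json.loads(Path(path).read_text())
    try:
        return PopulationEstimate(
            per_residue={str(k): float(v) for k, v in data["per_residue"].items()},
            p_A_mean=float(data["pA_mean"]),
            p_B_mean=float(data["pB_mean"]),
            p_B_sd=float(data["pB_sd"]),
            p_B_range=(float(data["pB_range"][0]), float(data["pB_range"][1])),
            K=float(data["K"]),
            delta_G=float(data["delta_G_kcal_mol"]),
            temperature=float(data["temperature_K"]),
            residues_used=[str(r) for r in data["residues_used"]],
            condition=str(data.get("condition", "")),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing report field {exc}") from exc
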