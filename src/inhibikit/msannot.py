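"""Negative-mode exact-mass ion annotation for small-molecule LC-MS.

Iridoid glycosides ionise best as deprotonated molecules [M - H]-, so the
module works entirely in that convention: the calculated ion is the neutral
monoisotopic mass minus the mass of a hydrogen *atom* (the ~0.5 mDa electron
mass is ignored, which is the convention the instrument software applied to
the reference values this module reproduces).  Beyond plain mass arithmetic
it provides ppm mass-accuracy errors, neutral-loss assignment against a
small user-extensible loss library (glucose residue, iridoid ring cleavage),
and the 3:1 M/M+2 intensity test that flags a single chlorine atom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._elements import HYDROGEN_ATOM_MASS, MONOISOTOPIC_MASS

__all__ = [
    "ElementalFormula",
    "AnnotatedIon",
    "NeutralLossAnnotation",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "deprotonated_mz",
    "ppm_error",
    "annotate_ion",
    "annotate_neutral_losses",
    "chlorine_cluster_flag",
    "DEFAULT_LOSS_LIBRARY",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulae."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# decorations that appear in publication tables: C_22_H_26_O_13_ etc.
_DECORATION = re.compile(r"[_\s]")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map over the CHNOS+Cl alphabet of plant metabolomics."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("formula must contain at least one atom")
        for element, n in self.counts:
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if n <= 0:
                raise FormulaError(f"non-positive count for element {element!r}")

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "ElementalFormula":
        return cls(tuple(sorted((e, int(n)) for e, n in counts.items() if n)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return ElementalFormula.from_dict(merged)

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        d = self.as_dict()
        parts = []
        for e in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if e in d:
                parts.append(f"{e}{d[e] if d[e] != 1 else ''}")
        return "".join(parts)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C22H27ClO13"``.

    Table decorations (underscores, whitespace) are stripped first, so the
    publication style ``"C_22_H_26_O_13_"`` parses identically.  Repeated
    element tokens accumulate.  Unknown symbols or stray characters raise
    :class:`FormulaError` naming the offending span.
    """
    cleaned = _DECORATION.sub("", text)
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: cannot parse at {cleaned[pos:pos + 4]!r}"
            )
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula.from_dict(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts)


def deprotonated_mz(formula: ElementalFormula | str) -> float:
    """Calculated [M - H]- m/z: monoisotopic mass minus one hydrogen atom.

    The electron mass is deliberately ignored (see module docstring); report
    to 4 decimals.  A formula without hydrogen cannot lose a proton.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if formula["H"] < 1:
        raise FormulaError(f"{formula} has no hydrogen to lose; [M - H]- undefined")
    return monoisotopic_mass(formula) - HYDROGEN_ATOM_MASS


def ppm_error(detected: float, calculated: float) -> float:
    """Signed mass accuracy (detected - calculated)/calculated in ppm."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return (detected - calculated) / calculated * 1e6


@dataclass(frozen=True)
class AnnotatedIon:
    """A detected negative-mode ion annotated with its formula assignment."""

    detected_mz: float
    calculated_mz: float
    ppm: float
    formula: ElementalFormula

    @property
    def calculated_mz_4dp(self) -> float:
        return round(self.calculated_mz, 4)

    @property
    def ppm_1dp(self) -> float:
        return round(self.ppm, 1)


def annotate_ion(detected_mz: float, formula: ElementalFormula | str) -> AnnotatedIon:
    """Build the full [M - H]- annotation for one detected ion."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    calc = deprotonated_mz(formula)
    return AnnotatedIon(detected_mz, calc, ppm_error(detected_mz, calc), formula)


@dataclass(frozen=True)
class LossEntry:
    """One library neutral loss: exact mass in Da, or nominal-only."""

    label: str
    mass: float
    nominal_only: bool = False


# The two losses diagnostic for iridoid glycosides: the glucose residue
# (C6H10O5, exact) and the 114 Da ring-cleavage loss (two aldehyde groups
# plus a 28 Da ring fragment; only its nominal mass is catalogued).
DEFAULT_LOSS_LIBRARY: tuple[LossEntry, ...] = (
    LossEntry("glucose moiety", 162.0528),
    LossEntry("ring cleavage", 114.0, nominal_only=True),
)


@dataclass(frozen=True)
class NeutralLossAnnotation:
    parent_mz: float
    fragment_mz: float
    loss_mass: float
    nominal_loss: int
    label: str | None = None
    mda_error: float | None = None

    def __post_init__(self) -> None:
        if self.loss_mass <= 0:
            raise ValueError("fragment m/z must be below parent m/z")


def annotate_neutral_losses(
    parent_mz: float,
    fragment_mzs: list[float],
    loss_library: tuple[LossEntry, ...] = DEFAULT_LOSS_LIBRARY,
    tol_mda: float = 10.0,
) -> list[NeutralLossAnnotation]:
    """Assign each fragment a neutral loss relative to *parent_mz*.

    Every fragment gets its nominal (integer-rounded) loss; a label is
    attached when an exact-mass library entry lies within *tol_mda* mDa of
    the observed loss, or when a nominal-only entry matches the nominal
    loss.  Unmatched losses are returned unlabelled, never dropped.
    """
    annotations = []
    for frag in fragment_mzs:
        loss = parent_mz - frag
        if loss <= 0:
            raise ValueError(
                f"fragment {frag} is not below parent {parent_mz}; not a neutral loss"
            )
        nominal = round(loss)
        label, mda = None, None
        for entry in loss_library:
            if entry.nominal_only:
                if nominal == round(entry.mass):
                    label, mda = entry.label, None
                    break
            else:
                err_mda = (loss - entry.mass) * 1e3
                if abs(err_mda) <= tol_mda:
                    label, mda = entry.label, err_mda
                    break
        annotations.append(
            NeutralLossAnnotation(parent_mz, frag, loss, nominal, label, mda)
        )
    return annotations


def chlorine_cluster_flag(
    intensity_m: float, intensity_m2: float, tol: float = 0.25
) -> bool:
    """True when the M/M+2 intensity ratio is within *tol* (relative) of 3.

    A single 35Cl/37Cl atom produces the characteristic quasimolecular 3:1
    isotope cluster; a missing M+2 peak simply means "no chlorine", not an
    error.
    """
    if intensity_m < 0 or intensity_m2 < 0:
        raise ValueError("intensities must be non-negative")
    if intensity_m2 == 0:
        return False
    ratio = intensity_m / intensity_m2
    return abs(ratio - 3.0) / 3.0 <= tol
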