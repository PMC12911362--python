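"""Monoisotopic masses, ppm matching, and analog mass-delta logic.

Supports the putative-identification arithmetic used for exact-mass
annotation: theoretical monoisotopic masses of molecular formulas in
neutral / anion / cation conventions, parts-per-million matching of observed
against expected m/z (default tolerance +/- 1 ppm), and signed mass deltas
between structural analogs — e.g. glucose 6-sulfate (C6H12O9S) vs glucose
6-phosphate (C6H13O9P), whose neutral masses differ by 0.0095 Da, or the
diagnostic phosphate fragment H2PO4 at 96.969.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MolecularFormula",
    "MassMatch",
    "monoisotopic_mass",
    "ppm_match",
    "analog_delta",
    "ELECTRON_MASS",
]

#: Monoisotopic masses of the most abundant isotope (Da), CODATA/IUPAC.
MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207117,
}

ELECTRON_MASS = 0.00054858

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class MolecularFormula:
    """Element-count map with optional charge and label."""

    elements: dict[str, int]
    charge: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("formula must contain at least one element")
        for el, n in self.elements.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}")

    @classmethod
    def from_string(cls, s: str, charge: int = 0, label: str | None = None):
        """Parse a Hill-style formula string like ``"C6H13O9P"``."""
        s = s.strip()
        elements: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {s!r} at {s[pos:]!r}")
            pos = m.end()
            el, count = m.group(1), int(m.group(2) or 1)
            elements[el] = elements.get(el, 0) + count
        if pos != len(s):
            raise ValueError(f"cannot parse formula {s!r} at {s[pos:]!r}")
        return cls(elements, charge=charge, label=label)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.elements)
        for el, n in other.elements.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged, charge=self.charge + other.charge)


def _as_formula(f) -> MolecularFormula:
    return f if isinstance(f, MolecularFormula) else MolecularFormula.from_string(f)


def monoisotopic_mass(formula, convention: str = "neutral") -> float:
    """Theoretical monoisotopic mass (Da; m/z for singly charged ions).

    ``convention``: ``neutral`` sums the atomic masses; ``anion`` adds one
    electron mass ([M-H]-style deprotonation is the caller's job — this is
    the charge-carrier correction only); ``cation`` subtracts one.
    """
    f = _as_formula(formula)
    unknown = sorted(set(f.elements) - set(MONOISOTOPIC))
    if unknown:
        raise ValueError(f"unknown element(s): {', '.join(unknown)}")
    mass = sum(MONOISOTOPIC[el] * n for el, n in f.elements.items())
    if convention == "neutral":
        return mass
    if convention == "anion":
        return mass + ELECTRON_MASS
    if convention == "cation":
        return mass - ELECTRON_MASS
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class MassMatch:
    observed_mz: float
    expected_mz: float
    ppm_error: float
    within_tolerance: bool
    tolerance_ppm: float = 1.0


def ppm_match(observed: float, expected: float, tolerance_ppm: float = 1.0) -> MassMatch:
    """Parts-per-million mass-accuracy match (boundary inclusive)."""
    if observed <= 0 or expected <= 0:
        raise ValueError("m/z values must be positive")
    ppm = 1e6 * (observed - expected) / expected
    return MassMatch(
        observed_mz=float(observed),
        expected_mz=float(expected),
        ppm_error=float(ppm),
        within_tolerance=bool(abs(ppm) <= tolerance_ppm),
        tolerance_ppm=tolerance_ppm,
    )


@dataclass
class AnalogDelta:
    delta_da: float
    observed_delta: float | None = None
    tolerance_da: float = 0.001
    matches: bool | None = None
    label: str = ""


def analog_delta(
    formula_a,
    formula_b,
    observed_delta: float | None = None,
    tolerance_da: float = 0.001,
) -> AnalogDelta:
    """Signed neutral-mass difference between two analogs (a - b).

    When an ``observed_delta`` is supplied, reports whether it matches the
    theoretical difference within an absolute tolerance (default 0.001 Da) —
    the logic used to confirm e.g. a sulfate-for-phosphate substitution from
    precursor masses.
    """
    fa, fb = _as_formula(formula_a), _as_formula(formula_b)
    delta = monoisotopic_mass(fa) - monoisotopic_mass(fb)
    matches = None
    if observed_delta is not None:
        matches = bool(abs(abs(observed_delta) - abs(delta)) <= tolerance_da)
    return AnalogDelta(
        delta_da=float(delta),
        observed_delta=observed_delta,
        tolerance_da=tolerance_da,
        matches=matches,
        label=f"{fa.label or ''} vs {fb.label or ''}".strip(),
    )
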