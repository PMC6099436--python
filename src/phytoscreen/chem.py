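"""Elemental-composition arithmetic and exact-mass utilities.

Everything downstream — candidate enumeration, isotope-pattern prediction,
ppm matching — rests on the monoisotopic masses computed here. The atomic
mass table is frozen in-code (IUPAC/CODATA values) so that theoretical m/z
values are bit-stable across platforms and library versions; positive-mode
ion masses subtract the electron mass, which matters at the fourth decimal
place for the compounds screened here (e.g. [M+H]+ of C17H17Cl2N is
306.0811, not 306.0816).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "ppm_error",
    "apply_delta",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
]

#: Monoisotopic atomic masses (Da) of the most abundant isotope, frozen.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Br": 78.9183371,
}

ELECTRON_MASS: float = 0.00054857990907

#: Mass of a proton = H atom minus one electron; added for [M+H]+ ions.
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition: element symbol -> non-negative count.

    Immutable and hashable; equality is element-wise. The all-zero
    ("empty") formula is valid and serializes to the empty string.
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __init__(self, counts: Mapping[str, int] | None = None):
        counts = dict(counts or {})
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int):
                raise ValueError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        object.__setattr__(self, "counts", items)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def hill(self) -> str:
        """Serialize in Hill order: C, H, then alphabetical (all
        alphabetical when carbon is absent). Count 1 is omitted."""
        d = self.as_dict()
        ordered: list[str] = []
        if "C" in d:
            ordered.append("C")
            if "H" in d:
                ordered.append("H")
            ordered.extend(sorted(e for e in d if e not in ("C", "H")))
        else:
            ordered.extend(sorted(d))
        return "".join(f"{e}{d[e] if d[e] != 1 else ''}" for e in ordered)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill()!r})"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C17H17Cl2N"``.

    Counts default to 1; repeated element symbols accumulate. Raises
    ``ValueError`` naming the offending symbol for unknown elements, and
    for any text not matching the element-count grammar.
    """
    if not isinstance(text, str):
        raise ValueError(f"formula must be a string, got {type(text).__name__}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (0.0 for the empty formula)."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f)


def protonated_mz(f: MolecularFormula) -> float:
    """m/z of the singly protonated ion [M+H]+.

    Adds one H atom and removes one electron mass. Rejects the empty
    formula: a bare proton is not a molecular ion.
    """
    if f.is_empty:
        raise ValueError("cannot protonate an empty formula")
    return monoisotopic_mass(f) + PROTON_MASS


def ppm_error(theoretical: float, measured: float) -> float:
    """Signed mass error in parts per million: (meas - theor)/theor * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (measured - theoretical) / theoretical * 1e6


def apply_delta(f: MolecularFormula, delta: Mapping[str, int]) -> MolecularFormula:
    """Element-wise addition of a signed count delta.

    Deltas commute; any element that would go negative raises
    ``ValueError`` identifying the deficient element.
    """
    counts = f.as_dict()
    for el, dn in delta.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol in delta: {el!r}")
        new = counts.get(el, 0) + dn
        if new < 0:
            raise ValueError(
                f"delta would make element {el} negative "
                f"({counts.get(el, 0)} {dn:+d} = {new})"
            )
        counts[el] = new
    return MolecularFormula(counts)
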