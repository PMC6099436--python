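"""Isotope-pattern prediction and halogen-envelope scoring.

A chlorinated compound betrays itself in a full-scan spectrum by its A/A+2
envelope: ~3:1 for one Cl (35Cl/37Cl abundance ratio 0.7576:0.2424) and
~9.8:6.3:1 for two (the field's "9:6:1" mnemonic). Patterns are computed by
n-fold convolution of per-element isotope distributions, aggregated into
nominal-mass bins (0.5 Da) — the resolution at which such envelopes are
read; fine isotope structure is out of scope. The abundance table is frozen
in-code for bit-stable output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem import MolecularFormula, PROTON_MASS

__all__ = [
    "ISOTOPES",
    "IsotopeDistribution",
    "Envelope",
    "isotope_pattern",
    "chlorine_signature",
    "envelope_match_score",
    "pattern_to_envelope",
    "CL_SPACING",
    "C13_SPACING",
]

#: Per-element isotopes as (mass Da, abundance) tuples, frozen (IUPAC 2013).
ISOTOPES: Mapping[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088989, 0.00364)),
    "O": ((15.9949146196, 0.99757), (16.9991317012, 0.00038), (17.9991610, 0.00205)),
    "F": ((18.99840322, 1.0),),
    "Na": ((22.9897692809, 1.0),),
    "P": ((30.97376163, 1.0),),
    "S": ((31.97207100, 0.9499), (32.97145876, 0.0075), (33.96786690, 0.0425),
          (35.96708076, 0.0001)),
    "Cl": ((34.96885268, 0.7576), (36.96590259, 0.2424)),
    "K": ((38.96370668, 0.932581), (39.96399848, 0.000117), (40.96182576, 0.067302)),
    "Br": ((78.9183371, 0.5069), (80.9162906, 0.4931)),
}

#: 37Cl - 35Cl mass difference: the A+2 spacing of chlorine envelopes.
CL_SPACING: float = 1.99705
#: 13C - 12C mass difference: the A+1 spacing.
C13_SPACING: float = 1.00336

_BIN_WIDTH = 0.5


@dataclass(frozen=True)
class IsotopeDistribution:
    """Isotopologue distribution: (mass, abundance) entries, masses strictly
    increasing, abundances summing to 1 before any pruning."""

    entries: tuple[tuple[float, float], ...]

    @property
    def masses(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.entries)

    @property
    def abundances(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.entries)

    @property
    def base_index(self) -> int:
        return max(range(len(self.entries)), key=lambda i: self.entries[i][1])


@dataclass(frozen=True)
class Envelope:
    """An isotope envelope as stick peaks with the base peak scaled to 1.0.

    ``mz`` values may be absolute (an observed feature) or relative offsets
    from the first peak (a theoretical signature); scoring only uses
    positions relative to the first peak, so the two interoperate.
    """

    mz: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self):
        if len(self.mz) != len(self.intensity) or not self.mz:
            raise ValueError("envelope needs equal-length, non-empty mz/intensity")
        if any(i <= 0 for i in self.intensity):
            raise ValueError("envelope intensities must be positive")
        if abs(max(self.intensity) - 1.0) > 1e-9:
            raise ValueError("envelope base peak intensity must be 1.0")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(m - self.mz[0] for m in self.mz)


def _bin_key(mass: float) -> int:
    return round(mass / _BIN_WIDTH)


def _convolve(a: dict[int, tuple[float, float]],
              b: dict[int, tuple[float, float]]) -> dict[int, tuple[float, float]]:
    """Convolve two binned distributions; entries are bin -> (abundance,
    abundance-weighted mean mass)."""
    out: dict[int, tuple[float, float]] = {}
    for ka, (pa, ma) in a.items():
        for kb, (pb, mb) in b.items():
            p = pa * pb
            m = ma + mb
            k = _bin_key(m)
            if k in out:
                p0, m0 = out[k]
                out[k] = (p0 + p, (m0 * p0 + m * p) / (p0 + p))
            else:
                out[k] = (p, m)
    return out


def _element_power(element: str, n: int) -> dict[int, tuple[float, float]]:
    """Distribution of n atoms of one element via binary exponentiation."""
    base = {_bin_key(m): (a, m) for m, a in ISOTOPES[element]}
    result: dict[int, tuple[float, float]] | None = None
    power = base
    while n > 0:
        if n & 1:
            result = power if result is None else _convolve(result, power)
        n >>= 1
        if n:
            power = _convolve(power, power)
    assert result is not None
    return result


def isotope_pattern(f: MolecularFormula, prune: float = 1e-4) -> IsotopeDistribution:
    """Theoretical isotopologue distribution of a neutral formula.

    Convolves per-element distributions and aggregates isotopologues into
    0.5 Da nominal-mass bins. Entries below ``prune`` x the base-peak
    abundance are dropped after normalization; the base peak itself can
    never be pruned.
    """
    if f.is_empty:
        raise ValueError("cannot compute an isotope pattern for an empty formula")
    if not 0 <= prune < 1:
        raise ValueError("prune must be in [0, 1)")
    dist: dict[int, tuple[float, float]] | None = None
    for el, n in f:
        part = _element_power(el, n)
        dist = part if dist is None else _convolve(dist, part)
    assert dist is not None
    entries = sorted((m, p) for _, (p, m) in dist.items())
    pmax = max(p for _, p in entries)
    entries = [(m, p) for m, p in entries if p >= prune * pmax]
    return IsotopeDistribution(tuple(entries))


def chlorine_signature(n_cl: int) -> Envelope:
    """Expected chlorine-only envelope for ``n_cl`` chlorine atoms.

    Binomial over 35Cl/37Cl, peaks at +1.99705 Da spacings, base peak 1.0.
    n_cl = 1 gives [1, 0.320]; n_cl = 2 gives [1, 0.640, 0.102] — the
    exact values behind the textbook "3:1" and "9:6:1" patterns.
    """
    if n_cl < 0:
        raise ValueError("number of chlorine atoms must be non-negative")
    p35, p37 = ISOTOPES["Cl"][0][1], ISOTOPES["Cl"][1][1]
    weights = [
        math.comb(n_cl, k) * p35 ** (n_cl - k) * p37 ** k for k in range(n_cl + 1)
    ]
    base = max(weights)
    return Envelope(
        mz=tuple(k * CL_SPACING for k in range(n_cl + 1)),
        intensity=tuple(w / base for w in weights),
    )


def pattern_to_envelope(dist: IsotopeDistribution, min_rel: float = 0.05,
                        charge_shift: float = PROTON_MASS) -> Envelope:
    """Reduce a neutral isotope distribution to the stick envelope expected
    in positive-mode data: peaks >= ``min_rel`` of the base, intensities
    relative to the base, m/z shifted by one proton."""
    amax = max(dist.abundances)
    peaks = [(m + charge_shift, a / amax) for m, a in dist.entries if a / amax >= min_rel]
    return Envelope(tuple(m for m, _ in peaks), tuple(i for _, i in peaks))


def envelope_match_score(observed: Envelope, expected: Envelope,
                         intensity_tol: float = 0.15,
                         mz_tol: float = 0.05) -> float:
    """Fraction of expected envelope peaks supported by the observation.

    Peaks are aligned by offset from each envelope's first (monoisotopic)
    peak. An expected peak is satisfied when an observed peak lies within
    ``mz_tol`` of its offset and the base-relative intensities differ by at
    most ``intensity_tol``. The score is (#satisfied / #expected):
    1.0 for a fully consistent envelope, dropping proportionally with each
    missing or intensity-deviant peak. Deterministic and order-independent.
    """
    if intensity_tol < 0 or mz_tol <= 0:
        raise ValueError("tolerances must be positive")
    obs = list(zip(observed.offsets, observed.intensity))
    matched = 0
    for off_e, int_e in zip(expected.offsets, expected.intensity):
        in_window = [(abs(off_o - off_e), int_o) for off_o, int_o in obs
                     if abs(off_o - off_e) <= mz_tol]
        if not in_window:
            continue
        _, int_o = min(in_window)
        if abs(int_o - int_e) <= intensity_tol:
            matched += 1
    return matched / len(expected)
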