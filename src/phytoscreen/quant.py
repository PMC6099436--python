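"""Quantification and provenance classification.

Parent drugs are quantified by external calibration (area vs. standard
concentration, ordinary least squares) and converted to a per-gram tissue
basis from the extraction parameters (1 g tissue in 2 mL solvent by
default). Metabolite provenance is inferred from the control design:
detection in the negative control means contamination; absence from the
growing-medium (GM) control means the plant made it; otherwise the
root/GM peak-area ratio arbitrates between plant metabolism (high ratio)
and plant-independent transformation followed by uptake (low ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

__all__ = [
    "CalibrationCurve",
    "QuantSummary",
    "ProvenanceCall",
    "PROVENANCE_CALLS",
    "fit_calibration",
    "quantify",
    "replicate_stats",
    "rsd_percent",
    "control_ratio",
    "classify_provenance",
    "translocation_factor",
]

PROVENANCE_CALLS = (
    "parent",
    "true_metabolite",
    "metabolite_dominant",
    "mixed",
    "transformation_leaning",
    "contamination_suspect",
)


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float          # area per (ug/L)
    intercept: float      # area
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class QuantSummary:
    mean: float           # ug/g
    sd: float             # ug/g, sample SD (n-1)
    rsd_percent: float    # reported rounded to integer
    n: int

    @property
    def rsd_rounded(self) -> int:
        return round(self.rsd_percent)


@dataclass(frozen=True)
class ProvenanceCall:
    compound: str
    call: str
    ratio: float | None = None   # root/GM area ratio, present iff GM-detected

    def __post_init__(self):
        if self.call not in PROVENANCE_CALLS:
            raise ValueError(f"unknown provenance call {self.call!r}")


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares calibration line from (concentration, area)
    pairs; requires at least two distinct concentration levels."""
    if len(points) < 2 or len({c for c, _ in points}) < 2:
        raise ValueError("calibration needs >= 2 distinct concentration levels")
    conc = [c for c, _ in points]
    area = [a for _, a in points]
    fit = stats.linregress(conc, area)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(points),
    )


def quantify(area: float, curve: CalibrationCurve, sample_mass_g: float = 1.0,
             extract_volume_l: float = 0.002) -> tuple[float, bool]:
    """Convert a peak area to ug per gram of tissue.

    ((area - intercept) / slope) gives the extract concentration in ug/L;
    multiplying by the extract volume and dividing by the extracted tissue
    mass yields ug/g. Returns (concentration, clipped): sub-intercept
    areas yield 0.0 with ``clipped=True``.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be positive")
    conc = (area - curve.intercept) / curve.slope * extract_volume_l / sample_mass_g
    if conc < 0:
        return 0.0, True
    return conc, False


def rsd_percent(mean: float, sd: float) -> float:
    """Relative standard deviation in percent (mean must be positive)."""
    if mean <= 0:
        raise ValueError("mean must be positive for an RSD")
    return sd / mean * 100.0


def replicate_stats(values: Sequence[float]) -> QuantSummary:
    """Mean, sample SD (n-1 denominator) and RSD% of replicate values."""
    n = len(values)
    if n < 2:
        raise ValueError("replicate statistics need at least 2 values")
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return QuantSummary(mean=mean, sd=sd, rsd_percent=rsd_percent(mean, sd), n=n)


def control_ratio(root_area: float, gm_area: float) -> float:
    """Root-extract / GM-control peak-area ratio.

    A zero GM area is not a number but a statement — "not detected in
    GM" — and is signalled as such rather than returned as infinity.
    """
    if gm_area == 0:
        raise ZeroDivisionError("not detected in GM control: no ratio defined")
    if gm_area < 0 or root_area < 0:
        raise ValueError("areas must be non-negative")
    return root_area / gm_area


def classify_provenance(
    compound: str,
    detected_root: bool,
    detected_leaf: bool,
    detected_gm: bool,
    detected_negative: bool,
    ratio: float | None = None,
    is_parent: bool = False,
    r_dominant: float = 100.0,
    r_mixed: float = 1.0,
) -> ProvenanceCall:
    """Map a detection pattern and root/GM ratio to a provenance call.

    Priority: negative-control detection -> contamination_suspect;
    administered compound -> parent; absent from GM -> true_metabolite;
    otherwise the ratio decides: >= ``r_dominant`` -> metabolite_dominant
    (plant metabolism overwhelmingly dominates), >= ``r_mixed`` -> mixed
    (both plant metabolism and external transformation contribute),
    below -> transformation_leaning. Total over its input lattice: every
    consistent flag/ratio combination maps to exactly one call.
    """
    if detected_gm and ratio is None:
        raise ValueError("GM-detected compound requires a root/GM ratio")
    if not detected_gm and ratio is not None:
        raise ValueError("ratio given but compound not detected in GM control")
    if detected_negative:
        call = "contamination_suspect"
    elif is_parent:
        call = "parent"
    elif not detected_gm:
        call = "true_metabolite"
    elif ratio >= r_dominant:
        call = "metabolite_dominant"
    elif ratio >= r_mixed:
        call = "mixed"
    else:
        call = "transformation_leaning"
    return ProvenanceCall(compound=compound, call=call,
                          ratio=ratio if detected_gm else None)


def translocation_factor(leaf_conc: float, root_conc: float) -> float:
    """Leaf/root concentration ratio: > 1 leaf-accumulating, < 1
    root-retained. Undefined (raises) for zero root concentration."""
    if root_conc <= 0:
        raise ValueError("translocation undefined for zero root concentration")
    return leaf_conc / root_conc
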