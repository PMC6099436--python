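"""Envelope assembly from centroided peak tables and suspect matching.

The pipeline's evidence unit is a *feature*: a monoisotopic peak plus the
co-eluting isotopologue peaks grouped with it. Features are matched to
suspect candidates by exact mass (ppm window) and by consistency of the
observed envelope with the candidate formula's theoretical pattern — the
latter is what keeps a lone noise peak from impersonating a dichlorinated
metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import ppm_error
from .isotopes import (C13_SPACING, CL_SPACING, Envelope, envelope_match_score,
                       isotope_pattern, pattern_to_envelope)
from .transforms import Candidate

__all__ = [
    "Feature",
    "MatchResult",
    "read_peak_table",
    "read_mzml",
    "assemble_envelopes",
    "match_suspects",
    "presence_table",
]

PEAK_COLUMNS = ("mz", "rt_min", "area", "sample_id", "compartment", "replicate")

#: Plausible isotopologue offsets from the monoisotopic peak (Da):
#: k1 x (13C-12C) + k2 x (37Cl-35Cl), up to two of each.
_ISO_OFFSETS = tuple(
    sorted(
        k1 * C13_SPACING + k2 * CL_SPACING
        for k1 in range(3)
        for k2 in range(3)
        if (k1, k2) != (0, 0)
    )
)


@dataclass(frozen=True)
class Feature:
    """A grouped isotope envelope in one sample."""

    mz: float                 # monoisotopic peak m/z
    rt: float                 # minutes
    area: float               # monoisotopic peak area
    envelope: Envelope        # absolute m/z, base (monoisotopic) = 1.0
    sample_id: str = ""
    compartment: str = ""
    replicate: int = 0

    @property
    def n_peaks(self) -> int:
        return len(self.envelope)


@dataclass(frozen=True)
class MatchResult:
    """A candidate <-> feature link passing all tolerances."""

    candidate: Candidate
    feature: Feature
    ppm: float
    envelope_score: float
    ambiguous: bool = False   # another candidate formula matched this feature
    isomer_index: int = 1     # 1-based, by RT, among features matching one candidate

    @property
    def rt(self) -> float:
        return self.feature.rt


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a centroided peak table (CSV or TSV) with columns
    mz, rt_min, area, sample_id, compartment, replicate."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(PEAK_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} lacks columns: {sorted(missing)}")
    for col, default in (("sample_id", path.stem), ("compartment", ""), ("replicate", 0)):
        if col not in df.columns:
            df[col] = default
    return df


def read_mzml(path: str | Path, sample_id: str = "", compartment: str = "",
              replicate: int = 0) -> pd.DataFrame:
    """Flatten centroided MS1 spectra of an mzML file into peak rows
    (scan start time -> rt_min). Requires pyteomics."""
    from pyteomics import mzml as _mzml

    rows = []
    with _mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            rt = float(spec["scanList"]["scan"][0]["scan start time"])
            for mz, inten in zip(spec["m/z array"], spec["intensity array"]):
                rows.append((float(mz), rt, float(inten)))
    df = pd.DataFrame(rows, columns=["mz", "rt_min", "area"])
    df["sample_id"] = sample_id or Path(path).stem
    df["compartment"] = compartment
    df["replicate"] = replicate
    return df


def assemble_envelopes(peaks: pd.DataFrame, rt_tol: float = 0.05,
                       mz_pair_tol: float = 0.01) -> list[Feature]:
    """Group co-eluting peaks at isotopologue spacings into features.

    Within each sample, peaks are scanned in ascending m/z; each not-yet
    grouped peak seeds a feature as its monoisotopic peak and absorbs every
    ungrouped peak that co-elutes within ``rt_tol`` minutes and sits within
    ``mz_pair_tol`` Da of an isotopologue offset (combinations of +1.00336
    and +1.99705, up to two each). Ungrouped peaks become singleton
    features. Empty input yields an empty list.
    """
    if rt_tol <= 0 or mz_pair_tol <= 0:
        raise ValueError("tolerances must be positive")
    features: list[Feature] = []
    if peaks.empty:
        return features
    for sample_id, group in peaks.groupby("sample_id", sort=True):
        g = group.sort_values(["mz", "rt_min"], kind="mergesort").reset_index(drop=True)
        mzs = g["mz"].to_numpy()
        rts = g["rt_min"].to_numpy()
        areas = g["area"].to_numpy()
        compartment = str(g["compartment"].iloc[0]) if "compartment" in g else ""
        replicate = int(g["replicate"].iloc[0]) if "replicate" in g else 0
        taken = [False] * len(g)
        for i in range(len(g)):
            if taken[i]:
                continue
            taken[i] = True
            members = [i]
            for j in range(i + 1, len(g)):
                if taken[j]:
                    continue
                dmz = mzs[j] - mzs[i]
                if dmz > _ISO_OFFSETS[-1] + mz_pair_tol:
                    break
                if abs(rts[j] - rts[i]) > rt_tol:
                    continue
                if min(abs(dmz - off) for off in _ISO_OFFSETS) <= mz_pair_tol:
                    taken[j] = True
                    members.append(j)
            base_area = areas[i]
            envelope = Envelope(
                mz=tuple(float(mzs[j]) for j in members),
                intensity=tuple(
                    min(float(areas[j]) / base_area, 1.0) if j != i else 1.0
                    for j in members
                ),
            )
            features.append(
                Feature(
                    mz=float(mzs[i]), rt=float(rts[i]), area=float(base_area),
                    envelope=envelope, sample_id=str(sample_id),
                    compartment=compartment, replicate=replicate,
                )
            )
    return features


def match_suspects(features: Sequence[Feature], candidates: Sequence[Candidate],
                   ppm_tol: float = 5.0, min_envelope_score: float = 0.7,
                   intensity_tol: float = 0.15, mz_tol: float = 0.05,
                   envelope_min_rel: float = 0.05) -> list[MatchResult]:
    """Match features against the suspect list.

    A match requires |ppm error| <= ``ppm_tol`` against the candidate's
    theoretical [M+H]+ m/z and an envelope score >= ``min_envelope_score``
    against the candidate formula's theoretical isotope envelope (peaks
    >= ``envelope_min_rel`` of base considered). Distinct retention times
    matching one candidate are reported as structural isomers, numbered by
    RT; features matched by more than one candidate formula are flagged
    ambiguous on every such match. Result order is deterministic and
    independent of input ordering.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    theo_envelopes: dict[str, Envelope] = {}
    for cand in candidates:
        key = cand.formula.hill()
        if key not in theo_envelopes:
            theo_envelopes[key] = pattern_to_envelope(
                isotope_pattern(cand.formula), min_rel=envelope_min_rel
            )

    raw: list[MatchResult] = []
    for feature in features:
        hits = []
        for cand in candidates:
            ppm = ppm_error(cand.theoretical_mz, feature.mz)
            if abs(ppm) > ppm_tol:
                continue
            score = envelope_match_score(
                feature.envelope, theo_envelopes[cand.formula.hill()],
                intensity_tol=intensity_tol, mz_tol=mz_tol,
            )
            if score < min_envelope_score:
                continue
            hits.append(MatchResult(cand, feature, ppm, score))
        ambiguous = len({h.candidate.formula for h in hits}) > 1
        raw.extend(replace(h, ambiguous=ambiguous) for h in hits)

    # isomer numbering: per candidate, distinct RTs ordered ascending
    by_cand: dict[tuple[str, str], list[MatchResult]] = {}
    for m in raw:
        by_cand.setdefault((m.candidate.name, m.candidate.formula.hill()), []).append(m)
    out: list[MatchResult] = []
    for _, group in sorted(by_cand.items()):
        rts = sorted({round(g.rt, 1) for g in group})
        for g in sorted(group, key=lambda m: (m.rt, m.feature.sample_id)):
            out.append(replace(g, isomer_index=rts.index(round(g.rt, 1)) + 1))
    out.sort(key=lambda m: (m.candidate.theoretical_mz, m.rt,
                            m.feature.compartment, m.feature.replicate,
                            m.feature.sample_id))
    return out


def presence_table(matches: Sequence[MatchResult]) -> pd.DataFrame:
    """Tidy per-match detection/area table across compartments.

    One row per (candidate, isomer RT, compartment, replicate) with the
    monoisotopic area; replicate areas are kept separate so downstream
    statistics (means, SDs, RSDs, control ratios) can be formed. An empty
    match list yields an empty table.
    """
    rows = [
        {
            "candidate": m.candidate.name,
            "formula": m.candidate.formula.hill(),
            "parent": m.candidate.parent,
            "isomer_index": m.isomer_index,
            "rt": m.rt,
            "theoretical_mz": m.candidate.theoretical_mz,
            "measured_mz": m.feature.mz,
            "ppm": m.ppm,
            "envelope_score": m.envelope_score,
            "compartment": m.feature.compartment,
            "replicate": m.feature.replicate,
            "sample_id": m.feature.sample_id,
            "area": m.feature.area,
            "detected": True,
            "ambiguous": m.ambiguous,
        }
        for m in matches
    ]
    columns = ["candidate", "formula", "parent", "isomer_index", "rt",
               "theoretical_mz", "measured_mz", "ppm", "envelope_score",
               "compartment", "replicate", "sample_id", "area", "detected",
               "ambiguous"]
    return pd.DataFrame(rows, columns=columns)
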