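"""Untargeted chlorine-signature screening.

Complements suspect screening: any feature whose envelope carries the
A/A+2(/A+4) intensity ratios of one or two chlorine atoms is flagged,
whether or not a suspect explains it. This is the route by which
unanticipated metabolites — e.g. amino-acid conjugates absent from any
literature list — surface from full-scan data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .isotopes import (Envelope, chlorine_signature, envelope_match_score,
                       isotope_pattern, pattern_to_envelope)
from .screening import Feature, MatchResult
from .transforms import Candidate

__all__ = ["HalogenHit", "detect_halogenated", "hits_to_frame"]


@dataclass(frozen=True)
class HalogenHit:
    feature: Feature
    n_cl_estimate: int
    signature_score: float
    matched_suspect: Candidate | None = None

    @property
    def is_unknown(self) -> bool:
        return self.matched_suspect is None


def detect_halogenated(
    features: Sequence[Feature],
    score_threshold: float = 0.7,
    n_cl_range: Sequence[int] = (1, 2),
    matches: Sequence[MatchResult] | None = None,
    intensity_tol: float = 0.15,
    mz_tol: float = 0.05,
    use_formula_when_known: bool = True,
) -> list[HalogenHit]:
    """Flag features whose envelopes look chlorinated.

    Each feature's envelope is scored against the pure-chlorine signature
    for every n in ``n_cl_range`` (A:A+2 = 1:0.320 for one Cl,
    A:A+2:A+4 = 1:0.640:0.102 for two); the best-scoring n with score >=
    ``score_threshold`` yields a hit. When ``matches`` are supplied, hits
    on suspect-explained features carry the suspect reference (and, with
    ``use_formula_when_known``, are scored against the suspect formula's
    full theoretical envelope, which folds the carbon contribution into
    A+2); the remainder are "unknown halogenated". Pure function of its
    inputs.
    """
    if not 0 <= score_threshold <= 1:
        raise ValueError("score_threshold must be in [0, 1]")
    suspect_of: dict[tuple[str, float, float], Candidate] = {}
    for m in matches or ():
        suspect_of.setdefault((m.feature.sample_id, m.feature.mz, m.feature.rt),
                              m.candidate)
    signatures: Mapping[int, Envelope] = {n: chlorine_signature(n) for n in n_cl_range}

    hits: list[HalogenHit] = []
    for feature in features:
        suspect = suspect_of.get((feature.sample_id, feature.mz, feature.rt))
        best_n, best_score = 0, -1.0
        for n, sig in signatures.items():
            if suspect is not None and use_formula_when_known and suspect.formula["Cl"] == n:
                expected = pattern_to_envelope(isotope_pattern(suspect.formula))
            else:
                expected = sig
            score = envelope_match_score(feature.envelope, expected,
                                         intensity_tol=intensity_tol, mz_tol=mz_tol)
            if score > best_score:
                best_n, best_score = n, score
        if best_n >= 1 and best_score >= score_threshold:
            hits.append(HalogenHit(feature, best_n, best_score, suspect))
    return hits


def hits_to_frame(hits: Sequence[HalogenHit]) -> pd.DataFrame:
    """CSV-ready summary: m/z, RT, estimated Cl count, score, assignment."""
    rows = [
        {
            "mz": h.feature.mz,
            "rt": h.feature.rt,
            "sample_id": h.feature.sample_id,
            "compartment": h.feature.compartment,
            "n_cl": h.n_cl_estimate,
            "score": h.signature_score,
            "suspect": h.matched_suspect.name if h.matched_suspect else "unknown",
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["mz", "rt", "sample_id", "compartment",
                                       "n_cl", "score", "suspect"])
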