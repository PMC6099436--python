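"""End-to-end orchestration: candidates -> features -> matches -> calls.

`run_pipeline` composes the stage modules over a directory of peak tables
(plus optional MS² and calibration files) and produces the report bundle:
a species table (the detected-compound analogue of a published detection
table: name, formula, RT, theoretical/measured m/z, ppm, fragments), a
halogen-hit table, a quantification summary for the calibrated parents,
and a provenance call per species. Deterministic given inputs + config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from hashlib import sha256
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .chem import parse_formula
from .halogen import HalogenHit, detect_halogenated, hits_to_frame
from .msms import (DEFAULT_DIAGNOSTICS, DEFAULT_LOSSES, annotate_losses,
                   flag_diagnostics, read_mgf)
from .quant import (ProvenanceCall, classify_provenance, fit_calibration,
                    quantify, replicate_stats)
from .screening import (Feature, MatchResult, assemble_envelopes, match_suspects,
                        presence_table, read_peak_table)
from .transforms import PARENT_DRUGS, Candidate, builtin_rules, enumerate_candidates

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_report"]

log = logging.getLogger("phytoscreen")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a screening run. Every tolerance must be positive."""

    parents: dict[str, str] = field(default_factory=lambda: dict(PARENT_DRUGS))
    max_depth: int = 3
    amino_acids: tuple[str, ...] = ("Phe", "Tyr")
    ppm_tol: float = 5.0
    rt_tol: float = 0.05                 # min; envelope co-elution window
    mz_pair_tol: float = 0.01            # Da; isotopologue spacing window
    fragment_tol: float = 0.1            # Da; MS2 fragment matching
    min_envelope_score: float = 0.7
    intensity_tol: float = 0.15
    envelope_mz_tol: float = 0.05
    halogen_score_threshold: float = 0.7
    r_dominant: float = 100.0            # root/GM ratio: plant metabolism dominates
    r_mixed: float = 1.0                 # below: transformation outside the plant
    sample_mass_g: float = 1.0
    extract_volume_l: float = 0.002
    rt_cluster_decimals: int = 1         # species identity = (formula, round(RT))

    def __post_init__(self):
        for name in ("ppm_tol", "rt_tol", "mz_pair_tol", "fragment_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        for name, fml in self.parents.items():
            parse_formula(fml)  # fail early, field-level

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("amino_acids",):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    candidates: list[Candidate]
    features: list[Feature]
    matches: list[MatchResult]
    match_table: pd.DataFrame        # tidy per-match rows (presence_table)
    species_table: pd.DataFrame      # one row per identified (formula, RT) species
    halogen_hits: list[HalogenHit]
    quant_table: pd.DataFrame        # per-parent per-compartment stats
    provenance: list[ProvenanceCall]
    msms_table: pd.DataFrame

    @property
    def n_species(self) -> int:
        return len(self.species_table)

    def provenance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"compound": p.compound, "call": p.call, "root_gm_ratio": p.ratio}
             for p in self.provenance],
            columns=["compound", "call", "root_gm_ratio"],
        )


def build_candidates(config: PipelineConfig) -> list[Candidate]:
    rules = builtin_rules(config.amino_acids)
    out: list[Candidate] = []
    for parent, formula in config.parents.items():
        out.extend(enumerate_candidates(parent, rules, max_depth=config.max_depth,
                                        parent_formula=formula))
    return out


def _load_peaks(input_dir: Path) -> pd.DataFrame:
    files = sorted(input_dir.glob("peaks*.csv")) + sorted(input_dir.glob("peaks*.tsv"))
    if not files:
        raise FileNotFoundError(f"no peak tables (peaks*.csv) in {input_dir}")
    return pd.concat([read_peak_table(f) for f in files], ignore_index=True)


def _species_key(formula: str, rt: float, decimals: int) -> tuple[str, float]:
    return formula, round(rt, decimals)


def run_pipeline(config: PipelineConfig, input_dir: str | Path) -> PipelineResult:
    """Run the full screen over every peak table in ``input_dir``.

    A *species* is a distinct (candidate formula, clustered RT) pair with
    at least one match in a root or leaf sample; isomers at distinct RTs
    therefore count separately. Provenance is called per species from its
    presence pattern across compartments and its root/GM mean-area ratio.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    log.info("phytoscreen %s | config %s", __version__, config.digest())
    log.info("config: %s", config.to_dict())

    peaks = _load_peaks(input_dir)
    candidates = build_candidates(config)
    features = assemble_envelopes(peaks, rt_tol=config.rt_tol,
                                  mz_pair_tol=config.mz_pair_tol)
    matches = match_suspects(
        features, candidates, ppm_tol=config.ppm_tol,
        min_envelope_score=config.min_envelope_score,
        intensity_tol=config.intensity_tol, mz_tol=config.envelope_mz_tol,
    )
    match_table = presence_table(matches)
    halogen_hits = detect_halogenated(
        features, score_threshold=config.halogen_score_threshold,
        matches=matches, intensity_tol=config.intensity_tol,
        mz_tol=config.envelope_mz_tol,
    )

    species_table = _build_species_table(match_table, config)
    provenance = _classify_species(match_table, species_table, config)
    quant_table = _quantify_parents(match_table, input_dir, config)
    msms_table = _annotate_msms(input_dir, config)

    log.info("identified %d species from %d features (%d matches)",
             len(species_table), len(features), len(matches))
    return PipelineResult(
        config=config, candidates=candidates, features=features, matches=matches,
        match_table=match_table, species_table=species_table,
        halogen_hits=halogen_hits, quant_table=quant_table,
        provenance=provenance, msms_table=msms_table,
    )


def _build_species_table(match_table: pd.DataFrame,
                         config: PipelineConfig) -> pd.DataFrame:
    """One row per identified species (detected in root or leaf)."""
    if match_table.empty:
        return pd.DataFrame(columns=["species", "formula", "rt", "theoretical_mz",
                                     "mean_measured_mz", "mean_ppm",
                                     "mean_envelope_score", "compartments"])
    plant = match_table[match_table["compartment"].isin(("root", "leaf"))]
    n_isomers = plant.groupby("candidate")["isomer_index"].max()
    rows = []
    for (formula, rt_key), grp in plant.groupby(
            [plant["formula"],
             plant["rt"].round(config.rt_cluster_decimals)], sort=True):
        all_rows = match_table[
            (match_table["formula"] == formula)
            & (match_table["rt"].round(config.rt_cluster_decimals) == rt_key)
        ]
        name = grp["candidate"].iloc[0]
        if n_isomers.get(name, 1) > 1:
            name = f"{name} (isomer {int(grp['isomer_index'].iloc[0])})"
        rows.append({
            "species": name,
            "formula": formula,
            "rt": rt_key,
            "theoretical_mz": grp["theoretical_mz"].iloc[0],
            "mean_measured_mz": grp["measured_mz"].mean(),
            "mean_ppm": grp["ppm"].mean(),
            "mean_envelope_score": grp["envelope_score"].mean(),
            "compartments": ",".join(sorted(all_rows["compartment"].unique())),
        })
    df = pd.DataFrame(rows).sort_values(["theoretical_mz", "rt"]).reset_index(drop=True)
    return df


def _classify_species(match_table: pd.DataFrame, species_table: pd.DataFrame,
                      config: PipelineConfig) -> list[ProvenanceCall]:
    calls: list[ProvenanceCall] = []
    parent_formulas = {parse_formula(f).hill() for f in config.parents.values()}
    for row in species_table.itertuples(index=False):
        sub = match_table[
            (match_table["formula"] == row.formula)
            & (match_table["rt"].round(config.rt_cluster_decimals) == row.rt)
        ]
        comp_areas = sub.groupby("compartment")["area"].mean()
        detected = set(sub["compartment"])
        ratio = None
        if "gm_control" in detected and "root" in detected:
            ratio = float(comp_areas["root"] / comp_areas["gm_control"])
        calls.append(
            classify_provenance(
                compound=row.species,
                detected_root="root" in detected,
                detected_leaf="leaf" in detected,
                detected_gm="gm_control" in detected,
                detected_negative="negative_control" in detected,
                ratio=ratio,
                is_parent=row.formula in parent_formulas,
                r_dominant=config.r_dominant,
                r_mixed=config.r_mixed,
            )
        )
    return calls


def _quantify_parents(match_table: pd.DataFrame, input_dir: Path,
                      config: PipelineConfig) -> pd.DataFrame:
    """External-calibration quantification for parents with a
    calibration_<parent>.csv present; replicate mean/SD/RSD per
    compartment."""
    rows = []
    for parent, formula in config.parents.items():
        cal_path = input_dir / f"calibration_{parent}.csv"
        if not cal_path.exists():
            continue
        cal = pd.read_csv(cal_path)
        curve = fit_calibration(
            list(zip(cal["concentration_ug_per_L"], cal["area"]))
        )
        hill = parse_formula(formula).hill()
        sub = match_table[(match_table["formula"] == hill)
                          & match_table["compartment"].isin(("root", "leaf"))]
        for compartment, grp in sub.groupby("compartment"):
            concs = [
                quantify(a, curve, config.sample_mass_g, config.extract_volume_l)[0]
                for a in grp.groupby("replicate")["area"].sum()
            ]
            if len(concs) < 2:
                continue
            s = replicate_stats(concs)
            rows.append({
                "compound": parent, "compartment": compartment,
                "mean_ug_per_g": s.mean, "sd_ug_per_g": s.sd,
                "rsd_percent": s.rsd_rounded, "n": s.n,
                "calibration_r2": curve.r_squared,
            })
    return pd.DataFrame(rows, columns=["compound", "compartment", "mean_ug_per_g",
                                       "sd_ug_per_g", "rsd_percent", "n",
                                       "calibration_r2"])


def _annotate_msms(input_dir: Path, config: PipelineConfig) -> pd.DataFrame:
    mgf = input_dir / "msms.mgf"
    columns = ["label", "precursor_mz", "fragment_mz", "annotation"]
    if not mgf.exists():
        return pd.DataFrame(columns=columns)
    rows = []
    for spectrum in read_mgf(mgf):
        annotations, unexplained = annotate_losses(
            spectrum, DEFAULT_LOSSES, tol=config.fragment_tol)
        diag_hits = flag_diagnostics(spectrum, DEFAULT_DIAGNOSTICS,
                                     tol=config.fragment_tol)
        noted: dict[float, list[str]] = {}
        for ann in annotations:
            noted.setdefault(ann.fragment_mz, []).append(
                "-" + " -".join(ann.losses))
        for frag_mz, diag in diag_hits:
            noted.setdefault(frag_mz, []).append(f"diagnostic:{diag.name}")
        for frag_mz in spectrum.fragment_mzs:
            rows.append({
                "label": spectrum.compound_label,
                "precursor_mz": spectrum.precursor_mz,
                "fragment_mz": frag_mz,
                "annotation": "; ".join(noted.get(frag_mz, ["unexplained"])),
            })
    return pd.DataFrame(rows, columns=columns)


def write_report(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the report bundle as TSV tables plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.species_table.to_csv(out_dir / "species.tsv", sep="\t", index=False)
    result.match_table.to_csv(out_dir / "matches.tsv", sep="\t", index=False)
    hits_to_frame(result.halogen_hits).to_csv(out_dir / "halogen_hits.tsv",
                                              sep="\t", index=False)
    result.quant_table.to_csv(out_dir / "quant.tsv", sep="\t", index=False)
    result.provenance_table().to_csv(out_dir / "provenance.tsv", sep="\t", index=False)
    if not result.msms_table.empty:
        result.msms_table.to_csv(out_dir / "msms_annotations.tsv", sep="\t", index=False)
    summary = {
        "phytoscreen_version": __version__,
        "config": result.config.to_dict(),
        "config_digest": result.config.digest(),
        "n_candidates": len(result.candidates),
        "n_features": len(result.features),
        "n_matches": len(result.matches),
        "n_species": result.n_species,
        "n_halogen_hits": len(result.halogen_hits),
        "n_unknown_halogen_hits": sum(h.is_unknown for h in result.halogen_hits),
        "provenance": {p.compound: p.call for p in result.provenance},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
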