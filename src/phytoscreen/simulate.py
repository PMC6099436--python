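"""Desk-scale synthetic LC-HRMS dataset emulating the cress experiment.

Generates centroided MS1 peak tables for root extracts, leaf extracts, a
growing-medium (GM) control and a negative control (three replicates
each), an MS² spectrum per compound, per-parent calibration tables, and a
ground-truth manifest. The embedded compounds are the three administered
antidepressants and their eleven observed metabolite species, each with
its full chlorine isotope envelope, ppm-scale mass jitter, log-normal
replicate variability, and a configurable number of random noise peaks.

The defaults encode the study conditions this generator emulates: three
culture replicates; 2 ppm mass accuracy; ~20% biological replicate
variability; root/leaf abundance ratios following the observed
translocation patterns (sertraline root-retained, trazodone
leaf-accumulating); GM-control trace levels set so the recomputed root/GM
area ratios land at the observed values (51, 378, 491, 1.84, 25); a
negative control containing nothing but noise. Noise peaks are placed so
they can neither match any default suspect candidate within 20 ppm nor
co-elute with any peak at an isotopologue spacing — noise is noise, by
construction, at every seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, parse_formula, protonated_mz
from .isotopes import C13_SPACING, CL_SPACING, isotope_pattern
from .msms import FragmentSpectrum, write_mgf
from .transforms import PARENT_DRUGS, builtin_rules, enumerate_candidates

__all__ = [
    "CompoundSpec",
    "SimConfig",
    "DEFAULT_COMPOUNDS",
    "COMPARTMENTS",
    "generate_dataset",
    "generate_msms",
    "generate_calibration",
    "CALIBRATION_SLOPE",
]

COMPARTMENTS = ("root", "leaf", "gm_control", "negative_control")

#: Area counts produced per (ug/L) of extract concentration by the
#: emulated detector; anchors peak areas to the calibration tables.
CALIBRATION_SLOPE = 100.0

# ug/g -> area: conc/volume(0.002 L) gives extract ug/L, times slope.
_UGG_TO_AREA = CALIBRATION_SLOPE / 0.002
#: Administered growing-medium concentration, 10 mg/L = 1e4 ug/L.
_GM_PARENT_AREA = 1e4 * CALIBRATION_SLOPE


@dataclass(frozen=True)
class CompoundSpec:
    """Ground truth for one embedded species.

    ``root_area``/``leaf_area`` are mean monoisotopic areas (arbitrary
    detector counts); the GM-control area is ``gm_fraction * root_area``
    (0 = absent from GM). ``expected_call`` is the provenance the
    classifier should recover.
    """

    name: str
    formula: str
    rt: float                                   # minutes
    root_area: float
    leaf_area: float
    gm_fraction: float
    fragments: tuple[tuple[float, float], ...]  # (m/z, relative intensity)
    is_parent: bool = False
    expected_call: str = "true_metabolite"

    def area_in(self, compartment: str) -> float:
        if compartment == "root":
            return self.root_area
        if compartment == "leaf":
            return self.leaf_area
        if compartment == "gm_control":
            return self.gm_fraction * self.root_area
        if compartment == "negative_control":
            return 0.0
        raise ValueError(f"invalid compartment label {compartment!r}")

    @property
    def mz(self) -> float:
        return protonated_mz(parse_formula(self.formula))


def _spec(name, formula, rt, root, leaf, gm_fraction, fragments, **kw):
    return CompoundSpec(name, formula, rt, root, leaf, gm_fraction,
                        tuple(fragments), **kw)


#: The 14 species observed in treated cress: 3 parents + 11 metabolites
#: (hydroxylation/demethylation products, the trazodone cleavage product
#: mCPP, and three amino-acid conjugates; OH-STR and OH-CLP occur as two
#: RT isomers each). Parent root/leaf areas encode the measured tissue
#: concentrations; metabolite areas are arbitrary but their root/GM ratios
#: reproduce the observed 51 / 378 / 491 / 1.84 / 25.
DEFAULT_COMPOUNDS: tuple[CompoundSpec, ...] = (
    _spec("STR", "C17H17Cl2N", 10.2, 4.29 * _UGG_TO_AREA, 0.52 * _UGG_TO_AREA,
          _GM_PARENT_AREA / (4.29 * _UGG_TO_AREA), [(275.0, 999.0)],
          is_parent=True, expected_call="parent"),
    _spec("OH-STR (isomer 1)", "C17H17Cl2NO", 6.7, 510000.0, 30000.0, 1 / 51,
          [(273.0, 999.0)], expected_call="mixed"),
    _spec("OH-STR (isomer 2)", "C17H17Cl2NO", 8.2, 80000.0, 2000.0, 0.0,
          [(273.0, 999.0)], expected_call="true_metabolite"),
    _spec("DM-STR + Phe", "C25H24Cl2N2O", 13.1, 15000.0, 0.0, 0.0,
          [(275.0, 999.0), (165.1, 700.0), (91.1, 350.0)],
          expected_call="true_metabolite"),
    _spec("DM-STR + Tyr", "C25H24Cl2N2O2", 12.7, 12000.0, 0.0, 0.0,
          [(275.0, 999.0), (181.1, 650.0), (107.1, 300.0)],
          expected_call="true_metabolite"),
    _spec("OH-DM-STR + Phe", "C25H24Cl2N2O2", 12.5, 10000.0, 0.0, 0.0,
          [(273.0, 999.0), (165.1, 600.0)], expected_call="true_metabolite"),
    _spec("CLP", "C19H23ClN2", 10.7, 1.83 * _UGG_TO_AREA, 1.14 * _UGG_TO_AREA,
          _GM_PARENT_AREA / (1.83 * _UGG_TO_AREA),
          [(270.1, 999.0), (242.1, 600.0), (86.1, 800.0)],
          is_parent=True, expected_call="parent"),
    _spec("DM-CLP", "C18H21ClN2", 10.4, 184000.0, 90000.0, 1 / 1.84,
          [(270.1, 999.0), (242.1, 550.0), (72.1, 700.0)],
          expected_call="mixed"),
    _spec("OH-CLP (isomer 1)", "C19H23ClN2O", 6.8, 378000.0, 150000.0, 1 / 378,
          [(313.2, 999.0), (86.1, 850.0)], expected_call="metabolite_dominant"),
    _spec("OH-CLP (isomer 2)", "C19H23ClN2O", 7.0, 491000.0, 180000.0, 1 / 491,
          [(313.2, 999.0), (86.1, 850.0)], expected_call="metabolite_dominant"),
    _spec("OH-DM-CLP", "C18H21ClN2O", 6.6, 60000.0, 20000.0, 0.0,
          [(299.1, 999.0), (86.1, 750.0)], expected_call="true_metabolite"),
    _spec("TZN", "C19H22ClN5O", 5.5, 0.91 * _UGG_TO_AREA, 2.63 * _UGG_TO_AREA,
          _GM_PARENT_AREA / (0.91 * _UGG_TO_AREA),
          [(176.1, 999.0), (148.1, 700.0)],
          is_parent=True, expected_call="parent"),
    _spec("OH-TZN", "C19H22ClN5O2", 6.3, 40000.0, 0.0, 0.0,
          [(176.1, 999.0), (148.1, 650.0)], expected_call="true_metabolite"),
    _spec("mCPP", "C10H13ClN2", 3.0, 50000.0, 25000.0, 1 / 25,
          [(154.0, 999.0)], expected_call="mixed"),
)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; a fixed seed yields byte-identical output."""

    seed: int = 42
    mass_jitter_ppm_sd: float = 2.0      # per-peak Gaussian m/z error
    intensity_noise_cv: float = 0.2      # whole-compound replicate variability
    envelope_noise_cv: float = 0.05      # per-isotopologue intensity jitter
    n_noise_peaks: int = 200             # random peaks per sample table
    replicates: int = 3
    compartments: tuple[str, ...] = COMPARTMENTS
    noise_mz_range: tuple[float, float] = (100.0, 600.0)
    noise_rt_range: tuple[float, float] = (0.5, 14.5)
    min_noise_ppm: float = 20.0          # noise distance from any candidate
    envelope_prune_rel: float = 1e-3
    candidate_depth: int = 3             # enumeration depth used for avoidance

    def __post_init__(self):
        for c in self.compartments:
            if c not in COMPARTMENTS:
                raise ValueError(f"invalid compartment label {c!r}")


@dataclass(frozen=True)
class SimResult:
    peaks: pd.DataFrame          # all samples, peak-table dialect
    manifest: dict

    def sample_tables(self) -> dict[str, pd.DataFrame]:
        return {sid: df.reset_index(drop=True)
                for sid, df in self.peaks.groupby("sample_id", sort=True)}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 log-normal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def _avoided_mzs(compounds: Sequence[CompoundSpec], config: SimConfig) -> np.ndarray:
    """Every [M+H]+ isotopologue m/z a noise peak must stay clear of:
    the full default candidate enumeration plus the embedded compounds."""
    formulas = {c.formula for c in compounds}
    for parent in PARENT_DRUGS:
        for cand in enumerate_candidates(parent, builtin_rules(),
                                         max_depth=config.candidate_depth):
            formulas.add(cand.formula.hill())
    mzs: list[float] = []
    for f in sorted(formulas):
        dist = isotope_pattern(parse_formula(f), prune=config.envelope_prune_rel)
        mzs.extend(m + PROTON_MASS for m in dist.masses)
    return np.sort(np.asarray(mzs))


_ISO_OFFSETS = np.array(
    sorted({k1 * C13_SPACING + k2 * CL_SPACING
            for k1 in range(3) for k2 in range(3) if (k1, k2) != (0, 0)})
)
_NOISE_RT_GUARD = 0.15     # min co-elution distance for offset checks, min
_NOISE_MZ_GUARD = 0.02     # Da around an isotopologue offset


def _noise_ok(mz: float, rt: float, avoided: np.ndarray, placed_mz: np.ndarray,
              placed_rt: np.ndarray, min_ppm: float) -> bool:
    # ppm distance to every candidate isotopologue
    i = np.searchsorted(avoided, mz)
    for j in (i - 1, i):
        if 0 <= j < len(avoided):
            if abs(mz - avoided[j]) / avoided[j] * 1e6 < min_ppm:
                return False
    if len(placed_mz):
        close = np.abs(placed_rt - rt) < _NOISE_RT_GUARD
        if close.any():
            dmz = np.abs(placed_mz[close] - mz)
            near = dmz[dmz < _ISO_OFFSETS[-1] + _NOISE_MZ_GUARD]
            for d in near:
                if np.min(np.abs(_ISO_OFFSETS - d)) < _NOISE_MZ_GUARD:
                    return False
    return True


def generate_dataset(
    config: SimConfig = SimConfig(),
    compounds: Sequence[CompoundSpec] = DEFAULT_COMPOUNDS,
    out_dir: str | Path | None = None,
) -> SimResult:
    """Generate per-compartment x replicate peak tables plus manifest.

    Each compound present in a compartment contributes its full [M+H]+
    isotope envelope (relative abundances from the isotope model, pruned
    at ``envelope_prune_rel``), scaled by a per-replicate log-normal
    factor (``intensity_noise_cv``) with per-isotopologue log-normal
    jitter (``envelope_noise_cv``), each peak's m/z perturbed by Gaussian
    ppm error. Noise peaks are rejection-sampled away from all candidate
    masses and from isotopologue spacings (module docstring). When
    ``out_dir`` is given, writes one ``peaks_<compartment>_r<k>.csv`` per
    sample, ``msms.mgf``, ``calibration_<parent>.csv`` per parent and
    ``manifest.json``.
    """
    rng = np.random.default_rng(config.seed)
    avoided = _avoided_mzs(compounds, config)
    envelopes = {
        c.formula: isotope_pattern(parse_formula(c.formula),
                                   prune=config.envelope_prune_rel)
        for c in compounds
    }

    rows: list[tuple] = []
    true_peaks: list[dict] = []
    for compartment in config.compartments:
        for rep in range(1, config.replicates + 1):
            sample_id = f"{compartment}_r{rep}"
            sample_mz: list[float] = []
            sample_rt: list[float] = []
            for comp in compounds:
                base = comp.area_in(compartment)
                if base <= 0:
                    continue
                base = base * float(_lognormal_factor(rng, config.intensity_noise_cv))
                dist = envelopes[comp.formula]
                amax = max(dist.abundances)
                n_peaks = 0
                for mass, abundance in dist.entries:
                    mz_theor = mass + PROTON_MASS
                    jitter = rng.normal(0.0, config.mass_jitter_ppm_sd)
                    mz = mz_theor * (1.0 + jitter * 1e-6)
                    rel = abundance / amax
                    peak_noise = (1.0 if rel == 1.0
                                  else float(_lognormal_factor(rng, config.envelope_noise_cv)))
                    area = base * rel * peak_noise
                    rows.append((mz, comp.rt, area, sample_id, compartment, rep))
                    sample_mz.append(mz)
                    sample_rt.append(comp.rt)
                    n_peaks += 1
                true_peaks.append({
                    "sample_id": sample_id, "compound": comp.name,
                    "formula": comp.formula, "mz": comp.mz, "rt": comp.rt,
                    "n_envelope_peaks": n_peaks,
                })
            placed_mz = np.asarray(sample_mz)
            placed_rt = np.asarray(sample_rt)
            lo_mz, hi_mz = config.noise_mz_range
            lo_rt, hi_rt = config.noise_rt_range
            accepted = 0
            attempts = 0
            noise_mz: list[float] = []
            noise_rt: list[float] = []
            while accepted < config.n_noise_peaks:
                attempts += 1
                if attempts > 200 * max(config.n_noise_peaks, 1):
                    raise RuntimeError("noise rejection sampling failed to converge")
                mz = float(rng.uniform(lo_mz, hi_mz))
                rt = float(rng.uniform(lo_rt, hi_rt))
                if not _noise_ok(mz, rt, avoided, placed_mz, placed_rt,
                                 config.min_noise_ppm):
                    continue
                area = float(rng.lognormal(mean=np.log(1e4), sigma=1.0))
                rows.append((mz, rt, area, sample_id, compartment, rep))
                noise_mz.append(mz)
                noise_rt.append(rt)
                placed_mz = np.concatenate([placed_mz, [mz]])
                placed_rt = np.concatenate([placed_rt, [rt]])
                accepted += 1

    peaks = pd.DataFrame(
        rows, columns=["mz", "rt_min", "area", "sample_id", "compartment", "replicate"]
    )
    manifest = {
        "config": asdict(config),
        "compounds": [
            {
                "name": c.name, "formula": c.formula, "mz": c.mz, "rt": c.rt,
                "is_parent": c.is_parent, "expected_call": c.expected_call,
                "areas": {comp: c.area_in(comp) for comp in config.compartments},
                "gm_fraction": c.gm_fraction,
            }
            for c in compounds
        ],
        "true_peaks": true_peaks,
        "n_species": len(compounds),
    }

    result = SimResult(peaks=peaks, manifest=manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample_id, df in result.sample_tables().items():
            df.to_csv(out_dir / f"peaks_{sample_id}.csv", index=False)
        write_mgf(generate_msms(compounds), out_dir / "msms.mgf")
        for parent, table in generate_calibration().items():
            table.to_csv(out_dir / f"calibration_{parent}.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def generate_msms(
    compounds: Sequence[CompoundSpec] = DEFAULT_COMPOUNDS,
    out_path: str | Path | None = None,
) -> list[FragmentSpectrum]:
    """One MS² spectrum per compound: precursor at the theoretical [M+H]+,
    fragments as specified (fixed intensities). Compounds without
    fragments yield an empty spectrum with a warning."""
    spectra = []
    for comp in compounds:
        if not comp.fragments:
            warnings.warn(f"compound {comp.name!r} has no fragments; empty spectrum")
        spectra.append(
            FragmentSpectrum(
                precursor_mz=comp.mz,
                fragments=tuple(comp.fragments),
                compound_label=comp.name,
            )
        )
    if out_path is not None:
        write_mgf(spectra, out_path)
    return spectra


def generate_calibration(
    parents: Mapping[str, str] = PARENT_DRUGS,
    slope: float = CALIBRATION_SLOPE,
    levels: Sequence[float] = (0.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0),
) -> dict[str, pd.DataFrame]:
    """Exact-linear external calibration tables (area = slope x ug/L)."""
    return {
        parent: pd.DataFrame(
            {"concentration_ug_per_L": list(levels),
             "area": [slope * c for c in levels]}
        )
        for parent in parents
    }
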