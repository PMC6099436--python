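# phytoscreen

Suspect and chlorine-isotope screening of drug metabolites in plant
LC-HRMS data.

When plants are exposed to pharmaceuticals — for instance through
irrigation with treated wastewater — they take the compounds up and
transform them: hydroxylation, N-demethylation, conjugation with amino
acids, and combinations of these. Detecting such metabolites in root and
leaf extracts from high-resolution mass spectrometry data, and deciding
whether each one was made *by the plant* or formed abiotically in the
growing medium, is the problem this package addresses. It is written for
analytical chemists and environmental scientists running
uptake/metabolism experiments of the kind performed with garden cress
(*Lepidium sativum*) exposed to the antidepressants sertraline (STR),
clomipramine (CLP) and trazodone (TZN).

## What it computes

**Exact masses.** For a sum formula $M$, the protonated molecular ion is
$m/z\,[\mathrm{M+H}]^+ = m_{\mathrm{mono}}(M) + m_\mathrm{H} - m_e$, from
a frozen table of monoisotopic atomic masses (the electron-mass
correction matters at the fourth decimal place). Mass accuracy is the
usual $\mathrm{ppm} = (m_\mathrm{meas} - m_\mathrm{theor}) /
m_\mathrm{theor} \times 10^6$.

**Suspect lists from biotransformation rules.** Candidates are generated
by breadth-first application of element-delta rules (hydroxylation $+$O,
demethylation $-$CH₂, amino-acid amide conjugation $+\mathrm{AA}
-\mathrm{H_2O}$) and product rules (the trazodone → mCPP piperazine-ring
cleavage) up to a configurable depth, or loaded from an explicit CSV
suspect list.

**Isotope envelopes.** Theoretical patterns come from n-fold convolution
of per-element isotope distributions in 0.5 Da nominal-mass bins. A
single chlorine gives A : A+2 = 1 : 0.320 ("3 : 1"), two chlorines
1 : 0.640 : 0.102 ("9 : 6 : 1") — the signature that both gates suspect
matches and drives the *untargeted* halogen screen that catches
metabolites no suspect list anticipated (e.g. amino-acid conjugates).

**MS² confirmation.** Fragments are annotated as the precursor minus up
to two stacked neutral losses (H₂O 18.0106, CH₃NH₂ 31.0422, an
amino-acid residue, ...), matched against the parent drug's spectrum
(shared fragments), and checked for diagnostic marker ions (m/z 165.1 =
conjugated phenylalanine, 181.1 = conjugated tyrosine).

**Quantification and provenance.** Parents are quantified by external
calibration (OLS) and replicate mean / SD / RSD. Each detected species is
classified from the control design: detected in the negative control →
contamination suspect; absent from the growing-medium (GM) control →
*true metabolite*; otherwise the root/GM peak-area ratio decides between
plant-metabolism-dominant (ratio ≥ 100), mixed origin, and
transformation-leaning (ratio < 1).

A synthetic-data module generates the full experiment at desk scale —
root/leaf/GM-control/negative-control peak tables with chlorine
envelopes, ppm mass jitter, replicate noise and decoy peaks, plus MS²
spectra, calibration tables and a ground-truth manifest — so the entire
pipeline is testable without instrument data.

## Worked example

```python
from phytoscreen import parse_formula, protonated_mz, ppm_error, chlorine_signature

f = parse_formula("C17H17Cl2N")            # sertraline
print(round(protonated_mz(f), 4))          # 306.0811
print(round(ppm_error(306.0811, 306.0823), 1))   # 3.9
print([round(i, 3) for i in chlorine_signature(2).intensity])
# [1.0, 0.64, 0.102]  — the dichloro "9:6:1" envelope, exactly
```

The full pipeline from the shell:

```bash
$ phytoscreen all --seed 42 --workdir run
14 species identified; report in run/report
```

`run/report/species.tsv` then lists each identified species with its
formula, retention time, theoretical and measured m/z and envelope score,
e.g. mCPP (C10H13ClN2, RT 3.0, measured m/z 197.0840) through OH-TZN and
the sertraline amino-acid conjugates; `provenance.tsv` carries the origin
calls with the recomputed root/GM ratios:

```
compound             call                 root_gm_ratio
mCPP                 mixed                26.6
DM-CLP               mixed                1.86
OH-DM-CLP            true_metabolite
OH-STR (isomer 1)    mixed                48.6
OH-STR (isomer 2)    true_metabolite
OH-CLP (isomer 1)    metabolite_dominant  381.1
...
```

Read: OH-DM-CLP and the second OH-STR isomer were never seen in the GM
control, so the plant made them; the first OH-STR isomer is abundant in
roots but also present in the GM at a ~49:1 ratio, so both plant
metabolism and plant-independent transformation contribute; the OH-CLP
isomers' ratios of several hundred mean the GM contribution is marginal.

See `docs/methods.md` for the model details, defaults and limitations.

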