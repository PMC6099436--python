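# Methods

This note documents the models, defaults and design choices behind
phytoscreen, and what the synthetic-data generator does and does not
emulate.

## Exact-mass model

Monoisotopic atomic masses are a frozen in-code table (IUPAC/CODATA, ≥ 8
significant figures: H 1.00782503207, C 12 exactly, N 14.0030740048,
O 15.9949146196, Cl 34.96885268, ...). Freezing the table keeps
theoretical m/z values bit-stable across platforms and library versions;
the test suite cross-checks it against pyteomics' independent table to
1e-5 Da. Positive ions subtract the electron mass (5.48580e-4 Da): for
C17H17Cl2N this is the difference between printing 306.0811 and 306.0816,
i.e. visible at the 4-decimal reporting precision of high-resolution
work. Only the [M+H]+ adduct is modeled — the compounds screened here are
basic amines measured in positive ESI and show no other adducts of
consequence; the adduct shift is a single constant and straightforward to
extend.

Two published conjugate m/z values (439.1330 for C25H24Cl2N2O; 455.1290
for C25H24Cl2N2O2) are not derivable from their own sum formulas (the
formula-derived values are 439.1338 and 455.1288). The package computes
the formula-derived values; the discrepancy is treated as a transcription
artifact in the source table, not forced into agreement.

## Isotope patterns

Patterns are computed by per-element binomial/multinomial convolution
(binary exponentiation per element, then cross-element convolution),
aggregating isotopologues into 0.5 Da nominal-mass bins with
abundance-weighted mean masses. This is exact at unit-mass resolution —
the resolution at which chlorine envelopes are read — and deliberately
ignores fine isotope structure; a test verifies the convolution against
brute-force enumeration over all isotopologue combinations to 1e-9.
Default pruning keeps entries ≥ 1e-4 of the base peak and can never
remove the base peak.

The chlorine signature is the Cl-only binomial: A : A+2 = 1 : 0.320 for
one Cl, 1 : 0.640 : 0.102 for two, at +1.99705 Da spacings. The envelope
match score is the fraction of expected peaks with an observed
counterpart within `mz_tol` (default 0.05 Da) whose base-relative
intensity deviates ≤ `intensity_tol` (default 0.15): simple,
deterministic, and monotone in envelope completeness. For CHNO-only
molecules up to 30 carbons the A+2/A ratio stays below 0.07 (two-¹³C plus
¹⁸O and minor cross terms), a five-fold margin below chlorine's 0.32, so
the screen's 0.7 score threshold cannot be reached without a halogen.
When a feature is already explained by a suspect, the halogen screen
scores against the suspect formula's full theoretical envelope (folding
the carbon A+2 contribution in); unknown features are scored against the
pure-Cl signature.

## Candidate enumeration

Rules are element deltas (hydroxylation +O; demethylation −CH₂, i.e. the
net change of removing an N-methyl; amino-acid conjugation + AA − H₂O,
modeling amide condensation without stereochemistry or attachment site)
plus one product rule for the trazodone → mCPP ring cleavage, which no
delta can express and which is therefore restricted to its substrate.
Enumeration is breadth-first to `max_depth` combined applications;
conjugation is capped at one application per chain. Chains reaching the
same formula are collapsed into one candidate retaining every distinct
chain as provenance — the mass spectrometer cannot distinguish them (a
demethyl-tyrosine conjugate and a hydroxy-demethyl-phenylalanine
conjugate share C25H24Cl2N2O2; telling them apart is MS² work). The
default depth is 3 with Phe/Tyr conjugation enabled, which covers every
observed metabolite class (e.g. OH + DM + conjugation); the full
proteinogenic amino-acid set is available by configuration.

As an alternative to rule enumeration, an explicit suspect CSV can be
loaded. The package ships a 21-entry list
(`data/suspects_reconstructed_synthetic.csv`) that is a synthetic
reconstruction of a typical literature-derived candidate set for these
parents — hydroxylated, demethylated, oxidized and conjugated
derivatives — intended as a realistic default and template, not as a
copy of any published supplementary table.

## Screening defaults

- `ppm_tol = 5`: the largest observed mass error in the reproduced
  detection table is 4.8 ppm.
- `rt_tol = 0.05 min`, `mz_pair_tol = 0.01 Da` for envelope assembly:
  co-elution and spacing windows comfortably wider than centroid jitter
  at 2 ppm but far tighter than chromatographic peak separation.
- `min_envelope_score = 0.7`: requires most of the theoretical envelope
  (peaks ≥ 5% of base) to be present with consistent intensities; a
  singleton peak at the right mass cannot pass it for any chlorinated
  formula.
- Ties (two candidate formulas within tolerance of one feature) are both
  reported and flagged ambiguous — no silent winner.

The published source states no ppm window or RT reproducibility; these
are engineering choices anchored to the observed errors, all exposed in
`PipelineConfig`.

## Quantification and provenance

Calibration is ordinary least squares on (concentration, area);
concentrations convert to µg/g via the extraction parameters (defaults:
1 g tissue, 2 mL solvent). Replicate SD uses the n−1 sample estimator
(the published values are consistent with either convention at n = 3
within rounding; n−1 is the statistical default). RSDs are reported
rounded to integers but kept at full precision internally.

Provenance thresholds: `r_dominant = 100`, `r_mixed = 1`. The source
gives no numeric cutoffs, only verbal calls; these defaults separate the
"only a very small GM contribution" cases (ratios of several hundred)
from the "both metabolism and transformation" cases (ratios ~2–50, with
1.84 explicitly called a both-mechanisms case, which places the lower
bound below it), while a ratio under 1 — more abundant in the GM than in
the root — genuinely suggests external transformation with uptake. They
are configuration, documented as interpretation rather than fact.
Negative-control detection overrides everything (contamination), and
administered parents are labeled as such regardless of ratio.

## Synthetic data: what it emulates, what it does not

The generator emulates the experimental design at desk scale: 3 culture
replicates × {root, leaf, GM control, negative control}; the 14 observed
species (3 parents + 11 metabolite species, two isomer pairs at distinct
RTs) with full isotope envelopes; Gaussian m/z jitter of 2 ppm SD
(observed errors span 0.5–4.8 ppm); whole-compound log-normal replicate
variability of CV 0.2 (observed biological RSDs 14–27%); small
per-isotopologue intensity jitter (CV 0.05) so envelopes are realistic
but not exact; 200 decoy noise peaks per sample. Replicate variability is
a *whole-compound* factor because biological variance scales the whole
chromatographic peak, not individual isotopologues; the per-isotopologue
CV is kept small because envelope ratios in real centroided data are far
more stable than absolute areas. Parent areas are anchored to the
measured tissue concentrations through the calibration slope; metabolite
areas are arbitrary (no raw areas are published — only ratios and
presence patterns are anchored), with GM trace fractions set to 1/51,
1/378, 1/491, 1/1.84 and 1/25 so the recomputed root/GM ratios land near
the reported values.

Noise peaks are rejection-sampled under two hard constraints: ≥ 20 ppm
from every isotopologue of every default-enumeration candidate, and never
co-eluting (within 0.15 min) with any peak at an isotopologue-like
spacing (±0.02 Da of combinations of 1.00336/1.99705). False positives
from noise are thus structurally impossible, at any seed — which is the
point: the end-to-end test checks the pipeline's wiring and tolerance
logic, not its robustness to adversarial backgrounds. Retention times are
fixed per compound (no drift), chromatographic peak shape, saturation,
matrix effects and in-source fragmentation are not simulated, and
absolute concentration recovery is only as good as the noiseless linear
calibration. Passing tests on this data therefore demonstrate correct
exact-mass/envelope/classification logic under the stated noise model;
they do not demonstrate performance on real extracts with RT drift,
co-elution or isobaric interference.

## Numerical details

- All randomness flows from one seeded `numpy` generator; a fixed seed
  gives byte-identical output files.
- Envelope assembly anchors each feature on the lowest-m/z peak of its
  group (for chlorinated, protonated small molecules the monoisotopic
  peak is the base peak).
- Species identity is (formula, RT rounded to 0.1 min); isomers at
  distinct RTs count as distinct species, matching how isomer pairs are
  reported separately in practice.
- MS² fragment tolerance is 0.1 Da, matching the one-decimal precision at
  which product ions are reported; at most two stacked neutral losses are
  considered (the deepest observed chain is CH₃NH₂ + H₂O).
- Degenerate inputs fail loudly: empty formulas cannot be protonated,
  calibration needs two distinct levels, a zero GM area signals "not
  detected" rather than returning infinity.

## Known limitations

No adducts beyond [M+H]+, no multiply charged ions, no positional-isomer
structure elucidation (isomers are distinguished by RT only), no
LOD/LOQ or matrix-effect modeling, no profile-mode peak picking (the
pipeline starts from centroided peak tables; mzML centroid import is
provided), and phase-II conjugates not observed in this system
(glucuronides, sulfates) are not default rules, though the rule set is
user-extensible.
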