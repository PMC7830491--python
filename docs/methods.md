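# Methods

## Scientific setting

Compound-specific isotope analysis of amino acids (CSIA-AA) measures δ¹⁵N
and δ¹³C of individual amino acids rather than bulk tissue. Two properties
make it a trophic tool: "source" amino acids (phenylalanine) barely
fractionate ¹⁵N per trophic transfer while "trophic" ones (glutamic acid)
enrich strongly, so their divergence encodes trophic position; and the
δ¹³C fingerprint of essential amino acids, which animals cannot synthesize,
traces the carbon source. The package emulates a controlled feeding
experiment on a symbiotic coral: six genetically distinct mother colonies,
three nutritional regimes (autotrophy, mixotrophy = light + *Artemia*
feeding, heterotrophy = darkness + feeding), and two tissue compartments
(animal host and dinoflagellate symbionts) separated by centrifugation,
with the *Artemia* prey itself measured as a reference.

## Tissue model

Each sample's (amino acid, element) value is drawn independently from
Normal(mean, SD) given by a (treatment, compartment, AA, element) parameter
table. The packaged `paper_defaults` table carries the published group
means ± SD for δ¹⁵N of Glu and Phe in both compartments and for the prey,
and the published prey δ¹³C values of the five essential amino acids used
for fingerprinting (valine, leucine, isoleucine, methionine,
phenylalanine). Two δ¹⁵N cells are unpublished and filled by stated
assumption (flagged in the config): host Phe, reported not to differ
between treatments, is set to 8.0 ± 1.3 ‰ everywhere; mixotrophic host Glu
is the midpoint of the autotrophic and heterotrophic host means
(9.6 ± 1.6 ‰). Tissue δ¹³C cells are reconstructed from the reported
anchors — isoleucine −18 ‰ autotrophic vs −22 ‰ under feeding, methionine
4 ‰ more negative under heterotrophy than autotrophy, all remaining cells
at a −26 ‰ baseline with SD 1.5 ‰ — applied identically to host and
symbiont because the two fractions' δ¹³C fingerprints are reported as
indistinguishable. An optional per-(colony, element) Normal(0, colony_sd)
offset models colony identity; it defaults to 0 because no variance
component is published.

By design the generator draws AAs independently; real CSIA-AA data show
correlated AAs within a sample (shared precursors, shared chromatography),
colony-level structure, and non-Gaussian tails. Passing tests therefore
demonstrate correctness of the *data-reduction arithmetic and statistical
machinery* under the stated distributional conditions, not robustness to
every feature of real chromatograms.

## Instrument model and its inversion

One injection sequence per element. Layout: a 3-injection certified-
standard block at the start, sample injections (duplicates for carbon,
triplicates for nitrogen — each injection measures all AAs of the sample),
a fresh standard block after at most 18 sample injections, and a final
block at the end. Channels:

* **Carbon.** Derivatization adds n_d exogenous carbons of composition
  δ_d, so the measured derivative is the moles-weighted mixture
  δ_cd = (n_c δ_c + n_d δ_d)/(n_c + n_d). Skeletal carbon counts n_c are
  textbook values; n_d is not dictated by the measurement principle and
  defaults to 4 for every AA, overridable per AA via the chemistry CSV.
* **Nitrogen.** No nitrogen is added during derivatization; the channel
  has an affine instrument response, measured = a + b·true (default
  a = 0.5 ‰, b = 0.98 — a realistic mild mis-response so the calibration
  stage does real work by default).
* Both channels add linear drift (default 0.01 ‰/injection) and Gaussian
  analytical noise per injection (defaults 0.3 ‰ C, 0.5 ‰ N — typical
  GC-C-IRMS single-injection precision).

Inversion proceeds in a fixed order: replicate averaging (the analysis
operates on one value per sample/AA, as replicate injections are pure
instrument replicates), then drift, then the element-specific calibration.

* **Drift** is estimated by pooling all standard injections, centering
  within amino acid (each AA has its own true level but shares the
  sequence-wide drift), and regressing the centered reading on the
  centered injection position. Peaks are restated at the position of the
  opening standard block; the constant this choice leaves over is absorbed
  by the downstream regression/correction factor, so the round trip is
  exact either way. A single standard block means drift cannot be
  estimated: it is skipped with a warning.
* **δ¹³C_dcorr** is estimated per AA from the mass balance applied to the
  certified standards, averaging the first and last standard blocks
  (amino acids combust with different efficiencies, so bracketing blocks
  are averaged rather than pooled with mid-sequence ones, which serve
  drift estimation only). Samples are then corrected by
  δ¹³C_c = ((n_c+n_d)·δ¹³C_cd − n_d·δ¹³C_dcorr)/n_c.
* **Nitrogen** is calibrated by one ordinary least-squares fit per
  sequence of certified on measured values across the standard AAs
  (bracketing blocks averaged per AA); fitting in this direction makes
  application a direct evaluation. Fit diagnostics (R², residual SD) are
  attached; fewer than two standard AAs, zero measured spread, or a
  non-positive slope are errors. The packaged standard mix holds seven
  AAs spanning −6.69 to +43.25 ‰ in δ¹⁵N; only the two high anchors are
  certified reference values, the other certified deltas are synthetic
  stand-ins (so labelled in the config) chosen to span that range.

Every stage is affine, so with zero analytical noise the chain inverts the
forward model exactly; the test suite asserts recovery below 1e−9 ‰ over
100 random instrument parameterizations, and unbiasedness within 3 SE with
noise on.

## Trophic position

TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β)/TDF + 1, with β = −0.36 ‰ (the Glu–Phe
offset in primary producers) and TDF = 4.54 ‰ per trophic level as
packaged defaults; other published constant sets can be supplied. TP is
reported per sample and then averaged per group — by linearity this
estimates the same quantity as TP of the group-mean deltas, and matches
how per-group TP distributions are usually displayed.

## Statistics

* δ¹⁵N responses are heteroscedastic across groups, so the battery runs
  Levene (median-centered) and Bartlett variance checks, then
  Kruskal–Wallis (midrank tie correction) with pairwise two-sided Wilcoxon
  rank-sum post hoc; the exact null is used for tie-free groups below
  n = 50, the tie-corrected normal approximation otherwise.
  Benjamini–Hochberg step-up adjustment is applied across each pairwise
  family. (Bartlett's test is sometimes mislabelled a normality test; it
  is a variance-homogeneity test and is implemented and reported as such.)
* Per-AA parametric comparisons use an additive two-way ANOVA (no
  interaction), sequential Type-I sums of squares in the order treatment
  then compartment, with Tukey HSD per factor at α = 0.05.
* The multivariate δ¹³C fingerprint over the five essential AAs is tested
  with a distance-based PERMANOVA implemented from first principles:
  Euclidean distances, Gower-centered inner-product matrix, sequential
  projection sums of squares for the additive two-factor model, pseudo-F
  against the full-model residual, and p by free permutation of sample
  rows (no strata), observed configuration included in numerator and
  denominator; default 999 permutations, seed mandatory. For n ≤ 9 an
  exact mode enumerates every permutation. A residual SS that is zero to
  relative precision is treated as exactly zero (infinite F) so that
  degenerate, perfectly separated configurations count permutation ties
  correctly. Mixotrophic samples are excluded from the multivariate
  comparison by default (their between-colony δ¹³C variability swamps the
  treatment signal); the treatment subset is configurable.
* Ordination is non-metric MDS (SMACOF with isotonic regression,
  normalized Kruskal stress-1), 20 random starts plus one classical-
  scaling start, best stress kept, seed recorded.

## Problem sizes and numerical choices

The default cohort is the study design itself (6 colonies × 3 treatments ×
2 compartments + 3 prey, ≈ 500 peaks across both sequences). Parameter-
recovery checks use 500 samples per group, calibration round-trip
tolerance is 1e−9 ‰ noise-free and 3 SE noisy, PERMANOVA null calibration
uses 1000 simulations at 99 permutations, and ensemble checks use five
seeds; at these sizes the whole suite runs in well under a minute.
Randomness flows from a single master seed through deterministically
spawned substreams.

A note on the trophic-position bound checks: with the published group SDs,
a single 6-sample group mean of TP has SE ≈ 0.26, so single-seed group
means fluctuate well beyond the published summary bounds; the bound checks
therefore evaluate group means pooled over the five-seed ensemble
(n = 30 per group), which is the scale at which the published summaries
are meaningful.

## Known limitations

* No chromatographic peak-shape or combustion-efficiency modelling beyond
  the linear response + drift; no size-effect (amplitude) nonlinearity.
* The generator's independence assumptions (across AAs and samples) are a
  simplification; PERMANOVA compartment-effect calibration on real,
  correlated data may differ.
* Derivatization carbon counts are a configurable convention, not
  measured chemistry; only results that are invariant to n_d (everything
  after correct inversion) should be interpreted.
* Exact reproduction of the original per-colony test statistics is not
  possible from published summaries; the package targets parameter
  recovery and qualitative pattern reproduction instead.
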