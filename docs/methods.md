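# Methods

This note documents the models, numerical choices and open design
decisions behind `pomewall`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Sodiated-ion mass model

Oligosaccharides released by the digests are modelled as unreduced
glycans ionized as `[M+Na]+` in positive mode — the dominant adduct for
neutral glycans on a DHB-type matrix. The molecular mass is the sum of
anhydro-residue masses plus one terminal water; no other adducts (K+,
H+) are modelled by default, though the residue-mass table is a plain
dataclass with a TSV override hook (`ResidueMassTable.from_tsv`) for
recalibration or alternative adducts.

Two mass scales are exposed deliberately:

* `sodiated_mass` — monoisotopic, assembled from atomic monoisotopic
  masses (H 1.00782503, C 12, O 15.99491462, Na 22.98976928) so that
  elementally identical compositions are exactly isobaric in floating
  point (Hex3a1 vs Pen4, both C20H32O16, m/z 569.169).
* `nominal_mz` — the sum of integer nominal residue masses (Hex 162,
  Pen 132, dHex 146, HexA 176, acetyl 42, methyl 14, water 18, Na 23).
  Fingerprint peaks are conventionally labelled on this scale. Rounding
  the monoisotopic mass is *not* equivalent above ~1.5 kDa: the
  per-residue mass defect accumulates past half a dalton, so XLFGa1 is
  monoisotopically 1597.51 but labelled 1597. The nominal scale
  reproduces all 34 labelled ions in the reference roster; rounded
  monoisotopic masses would mislabel two of them.

One roster entry, XLGa1 at m/z 1451, is internally inconsistent with the
letter grammar (XLGa1 computes to 995; 1451 corresponds to XLLGa1). The
package computes the grammatical value and the test suite asserts the
inconsistency is detected, not reproduced.

## Composition enumeration and annotation libraries

Inverse search (`enumerate_compositions`) is exhaustive over count
vectors within a family, bounded by structural ceilings rather than
tuned cutoffs:

* total glycosyl residues ≤ 12 (the digests produce DP 4–8 oligomers);
* acetyl esters ≤ backbone residues; methyl esters ≤ uronic acids;
* uronic acids ≤ pentoses — glucuronosyl units occur as substituents of
  the xylan backbone in these hydrolysates, never free;
* within the digest *series* libraries, the observed annotation space:
  hexo-oligomers DP 1–8 with 0–2 acetyls, pento-oligomers DP ≤ 5 with at
  most one glucuronosyl substituent and 0–2 acetyls.

The last group of ceilings matters for unique assignment: without them,
compositions never seen in these digests (e.g. Pen4U2m1, 0.037 Da from
Hex5a2) would occasionally out-compete true assignments under m/z
jitter. The `unconstrained` family deliberately ignores the series
ceilings and is the right mode for exploring ambiguity (it is what
reports the Hex3a1/Pen4 isobar).

Default m/z tolerance is ±0.3 Da. No tolerance is inherited from the
acquisition description, but external calibration with galactomannan
oligomers (DP 3–9) on a reflectron TOF supports sub-0.5 Da accuracy;
0.3 Da also cleanly separates the closest in-library pair. It is a CLI
flag, not a constant.

Reference-ion normalization divides all intensities by the digest's
reference peak (glucanase: m/z 1085/XXXG; mannanase: 731/Hex4a1;
xylanase: 655/Pen3U1a1). When several peaks fall within tolerance of the
reference m/z the most intense wins — reference ions are major
fragments, so the dominant candidate is the right one. The operation is
idempotent. The acquisition description also mentions normalizing ion
*masses* on the reference; there is no defined operation behind that
phrase, so only intensity normalization is implemented.

Replicate spectra stay separate rows in the intensity matrix; averaging
is an explicit downstream choice, since the sample axis of the original
fingerprint PCA (replicates vs means) is not documented.

## Composition accounting

Units are carried as explicit tags (`%AIM`, `%NSP`) and mixing unit
systems without conversion raises; this catches the classic error of
dividing a %NSP sugar by an %AIM denominator.

Degree of methylesterification uses methanol 32.042 g/mol against the
*anhydro*-galacturonosyl residue mass 176.126 g/mol (not the free acid,
194): the in-chain residue is what the uronic-acid assay measures, and
only this choice reproduces the published DM values from their own
methyl-ester/UA inputs (e.g. 2.8/22.4 → 68.7 vs printed 69.2, within the
2-significant-figure rounding of the inputs; across the five stages the
largest gap is 1.0 at the final storage stage).

Release fractions (released %NSP over initial %NSP) reproduce published
cells within the propagation of the inputs' one-decimal rounding: for a
cell like 0.3/4.4 the printed inputs only constrain the quotient to
about ±1.2 percentage points, so the reconstruction test uses the
propagated bound, floored at ±0.3 for well-determined cells.

Stage ANOVA is classical one-way fixed-effects at the study's strict
threshold p < 1e-4; the published a/b/c significance letters map to
two-group contrasts between the named stage pairs (60DAF vs H, H vs 2M,
60DAF vs 2M) at the same threshold.

## Transcriptome statistics

Two-colour normalization is MA-lowess (statsmodels lowess, frac 0.3 by
default) followed by quantile normalization. Quantile normalization maps
each rank to the cross-column mean of that rank, averaging over ties; it
is idempotent and rank-preserving, and after it all column distributions
are bit-identical. Background correction in the original processing
chain has no published estimator; `subtract_background` is a documented
stand-in (per-probe subtraction floored at a small positive constant so
log transforms stay finite), and the synthetic design generates
expression post-correction, so no conclusion rests on its exact form.

The moderated t-test estimates the variance prior (d0, s0²) by moment
matching on log s²_g: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the
theory gives E[e] = log s0² − ψ(d0/2) + log(d0/2) and Var[e] =
ψ′(d_g/2) + ψ′(d0/2), so d0 comes from a Newton inversion of the
trigamma function and s0² from the corrected mean. When the empirical
variance of e falls below ψ′(d_g/2) the prior is effectively infinite
and all genes share s0². A `prior_df` override exposes the limiting
cases (0 = ordinary t; ∞ = fully pooled) for testing and sensitivity
analysis. Under the null the p-values are uniform and the type-I rate at
α = 0.01 is within ±0.003 on 10⁴ genes — the property the selection step
(p < 0.01 between the first and last stages, split by effect sign)
depends on.

Clustering is agglomerative with distance 1 − Pearson r and average
(UPGMA) linkage via scipy; the Pearson distance makes results invariant
to per-profile affine rescaling, and scipy's linkage resolves ties
deterministically by lowest pair index. Zero-variance profiles are
rejected by name rather than silently dropped.

qPCR relative expression: the normalization factor is the arithmetic
mean Ct of three reference genes; ΔCt = Ct_target − Ct_ref, relative
expression 2^−ΔCt, and fold change between conditions 2^−ΔΔCt.

## Integration

PCA is an SVD of the centered (optionally unit-variance) matrix, with
loading signs fixed so each component's dominant entry is positive; a
test pins it to an eigendecomposition of the covariance matrix at 1e-8.

Genotype pooling averages expression over three fixed genotype pools
(Pool1: V034, I062, V083; Pool2: W029, I095, H097; Pool3: H074, I016)
per stage, yielding the 5 × 3 grid that pairs positionally with the
three biochemical replicates per stage.

Network edges need r > 0.7 and p < 0.01. Gene–gene networks are
positive-only (co-expression); biochemistry–transcript correlations use
absolute thresholds and keep the sign. No multiple-testing correction is
applied by default, matching the raw thresholds of the study design; a
Benjamini–Hochberg option would be a one-line addition to
`build_network` callers via statsmodels but is deliberately off. The
sample axis for gene–gene correlation is configurable (pooled 15-column
series by default in the drivers; the full 80-sample design in the
module-recovery tests) because the original description of "16 time
series" does not fix it.

## Synthetic data: what it emulates and what it does not

* **Spectra**: peaks at monoisotopic sodiated masses + Gaussian m/z
  jitter (default sd 0.05 Da), lognormal multiplicative intensity noise
  (cv 0.1), optional uniform decoy peaks kept ≥ 1 Da from planted ions.
  Default rosters mirror the digests' reported major ions with the
  reference ion dominant. Not emulated: isotope envelopes, baseline,
  detector saturation, in-source fragmentation.
* **Expression**: 5 stages × 8 genotypes × 2 plots; cluster A genes get
  a +2 log2 shift at the two early stages, cluster B at the three
  ripening/storage stages (5% of genes each), residual sd 0.5 — effect
  and noise chosen so the planted effect is a 4-sd shift, a clearly
  detectable but not trivial signal. Not emulated: dye bias (generated
  post-normalization), probe cross-hybridization, antisense probes,
  genotype-specific effects.
* **Biochemistry**: per-analyte linear stage templates between the
  published endpoints (Gal 18.7→7.2, UA 22.4→29.0, Xyl 4.8→7.6, Man
  4.4→3.1, Fuc 0.8→1.2 %NSP), 3 replicates, Gaussian noise; negative
  draws are resampled, never clipped, so the noise is truncated rather
  than massed at zero.

All generators are pure functions of (scenario, seed). Passing the
recovery tests shows the pipeline is correct and well-calibrated under
these idealized conditions; it does not show robustness to the
distortions listed as not emulated, and dataset-dependent headline
counts from the original study (probe-level expression rates, absolute
differential counts) have no synthetic analogue and are not asserted
anywhere.

## Problem sizes and determinism

The shipped analysis drivers use 1000 genes, 30 spectra (2 digests × 5
stages × 3 replicates) and 3 biochemical replicates per stage — the full
published design in breadth, with the gene count chosen to keep the
whole chain in seconds while leaving hundreds of null genes for
calibration checks. Statistical property tests use 10⁴ simulated null
genes. All randomness flows through explicit integer seeds; no stage
reads the clock. The pipeline runner writes a manifest (config hash,
seed, package version) and reruns with the same config are bit-identical.
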