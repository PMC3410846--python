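# Methods

This note documents the statistical procedures the package implements,
the choices made where several conventions exist, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Morphometrics

**View merging.** Dorsal and ventral digitizations of one skull share
four landmarks (ids 1, 2, 28, 29 by default).  The ventral view is mapped
into the dorsal frame by the least-squares rigid transform (Kabsch;
rotation + translation, determinant +1) fitted on the shared landmarks.
No scaling is estimated — both views digitize the same physical object,
so scale is shared by construction.  Shared landmarks take the average of
the two views; the RMS discrepancy over shared landmarks is reported as a
digitizing-error diagnostic.  Merging fails loudly when fewer than three
shared landmarks are present or they are collinear (the rotation is then
unidentifiable).

**Centroid size** is the square root of the summed squared deviations of
the landmarks from their centroid (mm).  The neurocranium size covariate
uses a configured landmark subset: the subset is an input (YAML), not a
hard-coded anatomy, because different landmark schemes delimit the
neurocranium differently.  The generator defines its own subset (the
midline landmarks plus the first four pairs).

**Object symmetry.** The symmetric component averages a configuration
with its relabeled reflection (left/right ids swapped, one coordinate
negated).  By default the reflected copy is first superimposed on the
original by a rigid fit, which makes the operation independent of the
configuration's orientation in space; with `align=False` the coordinate
plane itself is taken as the symmetry plane, in which case the operation
is the exact algebraic average (useful for controlled constructions, and
the form in which reflection-invariance holds identically).

**GPA.** Full generalized Procrustes: center, scale to unit centroid
size, rotate each configuration to the evolving consensus; the consensus
is re-normalized each round and iteration stops when it moves by less
than 1e-10 (Frobenius) or after 100 rounds.  Because a Procrustes
consensus is only defined up to a global rotation, the final
superimposition is rotated to a canonical frame: the principal axes of
the mean shape, signed so that the largest-magnitude loading on each
axis is positive (ties are not broken further; exactly isotropic mean
shapes are a measure-zero degeneracy).  This makes the output invariant,
to ≤1e-8, to arbitrary rotation/translation/rescaling of any input.
Specimens with missing landmarks are excluded with a warning rather than
imputed; no imputation rule is part of the procedure.

**Allometry.** The pooled within-group regression removes breed-sex
group means from both the shape coordinates and log neurocranium size,
fits one common slope vector, and reports the percentage of within-group
shape variance it explains.  Significance comes from permuting size
values *within* groups; the estimator is (b+1)/(n+1), which cannot
return zero.  The residuals handed to the PCA are the overall-centered
shapes minus the common allometric component — between-group differences
are retained, since they carry the trait signal the study maps.  (Removing
group means from the residuals, a tempting one-liner, silently deletes
the entire breed-level trait axis.)  Degenerate designs with singleton
groups have no within-group size variance; the pipeline then falls back
to pooling sexes within breed and logs the fallback.

**PCA.** Eigendecomposition (via SVD) of the specimen-level residual
covariance.  Sign convention: each loading's largest-|entry| is positive.
Specimen-level covariance is used throughout; no breed weighting.

## Association

The unit of analysis is the individual dog carrying its breed-sex average
phenotype (and, optionally, log neurocranium size as a covariate).  Sex
is not a covariate: the phenotype is already sex-averaged.  SNP QC keeps
markers with missingness strictly below 0.10 and MAF strictly above
0.01.  Dogs whose breed-sex cell has no phenotype are dropped (an
opposite-sex fallback exists but is off by default).

The OLS scan computes per-marker Wald t-tests with marker-wise deletion
of missing calls.  The mixed model is EMMA-style: eigendecompose the
centered kinship K = ZZᵀ/m once (missing dosages mean-imputed inside K
only), rotate y, covariates and each marker into the eigenbasis, and
profile the restricted likelihood over log(σ²_g/σ²_e) by bounded scalar
search on [−5, 5] (tolerance 1e-6), re-estimated per marker.  β is
tested with a t statistic on n−p degrees of freedom, so K = cI collapses
exactly to OLS.  REML rather than ML, and Wald rather than LRT, are the
standard defaults for this model class.  X-chromosome markers are treated
like autosomes — a documented limitation, not a modelling claim.

Genome-wide significance is Bonferroni, −log₁₀(α/m) at α = 0.05 over the
post-QC marker count.  Breed stratification supports three modes: breeds
strictly below the median log size; a named drop list; and an "extreme
brachycephaly" rule that removes breeds whose PC1 averages exceed 0.15
in both sexes.

On breed-constant phenotypes the calibrated mixed model has an effective
sample size near the number of breeds, which caps simultaneous per-QTL
power; the discovery role therefore falls to the OLS scan (whose
inflation is the price of that power), with the mixed model providing
relatedness-robust confirmation.  The test suite measures both roles:
OLS five-QTL recovery at Bonferroni, and mixed-model type-I calibration
on structured nulls.

## Selection scans

H_O is the fraction of heterozygous calls among non-missing calls per
SNP within a breed group.  H_R is examined as log₁₀(H_O,dolicho /
H_O,brachy); the base is configurable, the pseudocount defaults to 0 with
zero-valued terms flagged undefined rather than fudged.  F_ST defaults to
Hudson's two-population estimator (sample-size robust), with the Nei
(H_T−H_S)/H_T variant available; estimates are clipped to [0, 1] and
markers monomorphic in both groups are undefined.  Windows are means of
k = 10 consecutive markers advanced by 1, never spanning chromosomes;
windows with more than 20% undefined markers are flagged.  Tail flagging
uses mid-rank empirical percentiles over the genome-wide window
distribution; tails are open, so an all-equal distribution flags nothing.
Default tails: top 5% for F_ST, lowest 0.2% for the log H_O ratio.

## Critical intervals

The EM phaser works on windows of at most 12 bi-allelic markers over the
explicit 2^m haplotype space: the E-step distributes each genotype over
its compatible ordered haplotype pairs, the M-step re-estimates
frequencies; convergence at a maximum frequency change below 1e-8 (500
iterations cap), haplotypes below 1e-6 pruned.  Frequencies are estimated
pooled and per breed.  This is deliberately *not* a reimplementation of a
cluster-based phaser: the package's contribution is the interval logic,
which also accepts pre-phased haplotypes.

The haplotype-sharing interval is the longest run of consecutive markers
on which every contributing haplotype (frequency ≥ `min_freq` in each
target breed) carries identical alleles; ties break to the leftmost run.
Endpoints are the 1-based positions of the run's first and last marker;
BED export converts to 0-based half-open.

Breakpoint refinement scans the interval's positions in ascending order
comparing two genomes' diploid genotypes: heterozygous vs homozygous
counts as disagreement, missing in either genome is skipped.  The refined
interval ends at the last agreeing position before the first
disagreement.  Reporting the last *agreeing* marker position is a stated
convention — describing the same breakpoint by the last agreeing position
or the first disagreeing one differs by one marker, and the convention
here is the former.  A panel-confirmation report tabulates shared-allele
chromosome counts at diagnostic markers.

## Variant filtering

Filters are applied in sequence and each sets an independent flag:

* GQ masking: per-sample genotypes with quality strictly below 8 become
  missing.  The strict-below convention is one of two defensible readings
  of "below 8" vs "≤ 8 reset"; the threshold and comparison are
  configurable.
* Association: additive regression of the panel phenotype on dosage per
  variant, excluding a designated outlier genome; the `associated` flag
  marks p-values in the smallest 5% by mid-rank percentile.  The
  denominator is the set of evaluable (post-masking, polymorphic)
  variants.
* Conservation: flag at score ≥ 0.7.  ("Above 0.7" vs "≥ 0.7" conflict in
  the sources; ≥ is implemented and configurable.)
* Gene context: exon endpoints inclusive, UTRs count as exonic; the
  splice flag covers intronic positions 1–20 bp from an exon boundary
  that is an actual splice junction (first-exon starts and last-exon ends
  are transcript ends, not junctions).

`of_interest` = inside the active interval AND any criterion flag; the
combination is monotone under threshold tightening.  Codon annotation
maps a genomic SNV through the exon structure to its codon and offset,
respecting strand (alt alleles complemented on minus-strand genes), and
translates by the standard code, reporting `F452L`-style notation,
synonymous (`G12=`), stop-gain and stop-loss.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Population structure**: 60 breeds × 8 dogs, Balding–Nichols drift
  from Beta(1.2, 1.2) ancestral frequencies (clipped to [0.05, 0.95])
  through 6 clades (F = 0.08 ancestral→clade, 0.15 clade→breed), 10
  chromosomes × 100 SNPs at 50 kb spacing.  The two-level hierarchy
  produces the breed-clade kinship confounding the mixed model must
  absorb.
* **Trait**: five QTL markers (mid-chromosome on chromosomes 1–5) with
  effects (1.0, 0.95, 0.9, 0.85, 0.8); the trait is breed-level — effects
  times the breed mean dosage plus a breed effect (sd 0.25) and noise (sd
  0.05), standardized to a PC1-like scale (sd 0.12).  QTL per-breed
  allele frequencies are drawn U-shaped, Beta(0.2, 0.2): causal alleles
  of a selected trait are strongly differentiated across breeds, near
  fixation in phenotype-extreme breeds — unlike neutral drift markers.
  Effects of comparable magnitude reflect a trait whose mapped loci were
  all individually detectable.
* **Landmarks**: a fixed bilaterally symmetric 51-landmark template (5
  midline + 23 pairs), deformed along one symmetric unit axis in
  proportion to the trait, plus an allometric axis scaled by log relative
  size (coefficient 0.04), plus isotropic noise (sd 0.006 per coordinate
  in unit-shape scale).  Sizes are log-normal (sd 0.12) with a mild
  negative trait coupling (−0.15: brachycephalic breeds run smaller),
  base skull 120 mm.  Each specimen is emitted as dorsal + ventral views
  in independent random frames, exercising the merge step.  Under these
  defaults PC1 explains ~55–65% of residual shape variance and correlates
  with the planted trait at |r| ≥ 0.95.
* **Sweep**: within ±5 markers of the first QTL, chromosomes of the
  top-7 trait breeds are replaced by one haplotype with probability 0.95.
* **Resequencing panel**: 11 genomes over the 190 kb interval (CanFam2-
  style coordinates on the canine chromosome-32 locus this design
  emulates), 452 SNVs in the
  85.7 kb refined segment plus 250 downstream; the brachycephalic
  genomes share one haplotype up to the breakpoint, beyond which the
  lead genome is recombinant (a guaranteed disagreement right after the
  breakpoint makes the refinement sharp).  Per-sample GQ with 8% of
  calls below the masking threshold; ~10% of conservation scores ≥ 0.7;
  one causal missense variant (TTC→TTA at codon 452 of the interval
  gene) carried homozygous by the brachycephalic members and the outlier
  breed.

All draws flow from one seed through fixed per-stage substreams
(integer-seeded PCG64), so outputs are bit-identical for a given config
regardless of which stages run, on any platform.

**What the generator does not emulate** — and what passing tests
therefore do not show about real data: linkage disequilibrium and
recombination maps (markers are exchangeable within chromosomes, so
sweep signatures are cleaner than reality), measurement error structure
of a physical digitizer, phenotype-biased museum sampling, allele-calling
error outside the GQ model, overlapping gene architectures, and
population admixture between breeds.

## Numerical choices and degenerate inputs

GPA convergence 1e-10/100 iterations; canonical-frame tie-breaks as
above.  Permutation p-values use (b+1)/(n+1).  OLS/LMM declare a fit
degenerate (p = 1) when the residual sum of squares is at floating-point
noise level, as with a constant phenotype.  The LMM rejects kinship
matrices with eigenvalues below −1e-6 (relative); small negative
eigenvalues are clipped to zero.  EM windows above 12 markers are
refused rather than silently truncated.  Interval operations require
sorted positions and fail on reversed endpoints.  Percentile ties share
mid-ranks everywhere (windows and variant association alike).

## Pipeline

Stages exchange plain files (CSV/TSV/VCF/GFF3/BED/BedGraph) in one run
directory; a JSON manifest records the config hash, seed, stage
inputs/outputs and package version.  Re-running a config+seed reproduces
byte-identical tables; `--resume` skips stages whose recorded outputs
exist.  The interval stage picks the best-associated marker inside
windows flagged by *both* sweep statistics (high F_ST and low selected-
breed H_O) before falling back to the global top hit — the same
"associated locus with selection evidence" logic a study would apply.

## Problem sizes

Default test and acceptance runs use the generator defaults above
(480 dogs, ~1000 SNPs, 240 specimens, 702 panel variants) and 20 seeded
replicates for the recovery/detection rates; the structured-null
calibration uses a 2000-marker genome.  These sizes were chosen so the
statistical properties of interest (recovery, calibration, tail ranking)
are measured with adequate replication while the whole suite stays
interactive.

## Known limitations

No LD-aware phasing or imputation; no haplotype-based association; no
permutation-based genome-wide thresholds; X treated as autosomal; indel
consequences not annotated; the EM phaser is exponential in window size
by design and capped at 12 markers.
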