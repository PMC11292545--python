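# Methods

## The analysis model

`pepiso` analyses label-free DIA/SWATH quantification at the peptide level.
Its inputs are (a) a peptide-by-sample table of summed fragment/peptide
areas, (b) a map from each peptide (sequence + modification string) to the
set of protein accessions its evidence supports, and (c) a two-cohort sample
design.  The map may come from a search engine's distinct-peptide summary or
be derived from an isoform-aware FASTA by in-silico tryptic digestion
(classical rule: cleave C-terminal to K/R unless followed by P; fully
tryptic peptides with up to a configurable number of missed cleavages,
length-filtered).

Isoform families follow the UniProt convention: accessions `P-1`, `P-2`, …
are isoforms of canonical `P`; an accession without a terminal `-<integer>`
suffix is its own canonical.  Against this catalog every peptide receives
exactly one of four sharing classes (`UNIQUE`, `ISOFORM_SPECIFIC`,
`SHARED_ISOFORMS`, `SHARED_MULTI`); the classes partition the peptides, and
the classification is equivalent to direct enumeration of family
membership (property-tested against a brute-force oracle).

Peptides with identical accession sets are pooled into protein groups.  The
group area in a sample is the sum of member peptide areas observed there; a
group is missing in a sample only when every member is missing.  Summation
conserves total signal: per sample, the sum of group areas equals the sum of
classified peptide areas (up to 1e-6 relative; under the exclusion policy,
minus the areas of dropped multi-family peptides).

Two analysis branches share one composition and one normalization pass:

* **whole-protein differential abundance** — `SHARED_MULTI` groups are
  excluded (gene-level ambiguous evidence must not drive protein-level
  claims);
* **isoform analysis** — all groups retained, because the discordance call
  *requires* the splicing-blind `SHARED_ISOFORMS` group as its reference.

Because groups are keyed by the accession set itself, a multi-family shared
peptide can never pool with other peptides; excluding it before or after
composition yields the same group structure, which is why a single
composition serves both branches.

## Normalization

Group areas are log2 transformed (zeros must already be encoded as missing;
the reader's default policy maps exported `0` cells to missing, since a
non-detection is absence of evidence rather than a measured zero).  Each
sample column is then centered by subtracting its median over present
values; the even-count median is the mean of the two central order
statistics.  Median centering removes multiplicative loading/acquisition
offsets exactly: it is idempotent, and adding any constant to a sample's
log2 column leaves the normalized matrix unchanged (both are tested).

## Statistics

**Two-sample test.**  Per group, a two-sided equal-variance (pooled)
Student's *t* on normalized log2 values, df = n_A + n_B − 2.  A group is
*testable* when each cohort contributes at least `min_obs_per_group`
(default 3) observed values.  Degenerate limits are fixed: both cohorts
constant and equal gives t = 0, p = 1; both constant and unequal is an
error in the scalar API and p = 0 in the vectorised permutation path.
Welch's correction is deliberately not the default (the classical workflow
this package mirrors used the pooled test); the log2 fold change is
mean_B − mean_A, reported as fold = 2^|log2fc| with a direction label.

**Differential filter.**  Significant ⇔ p < `p_de` (default 0.05) and
fold ≥ `fc_de` (default 2).

**Permutation FDR.**  For B cohort-label permutations (all distinct label
splits enumerated exhaustively whenever their number is ≤ B; otherwise B
seeded random splits), all per-group p-values are recomputed under each
permuted labelling.  For a group with observed p,

    q(p) = [ mean over permutations of #{null p-values ≤ p} ]
           / #{observed p-values ≤ p},

clipped to [0, 1] and made monotone nondecreasing in p.  On designs small
enough to enumerate, the implementation equals an independently coded
brute-force oracle exactly.  Under the global null the procedure is
calibrated: the fraction of features with p < α matches α, and the fraction
with q < 0.05 stays at or below 0.05 (both within 3 binomial SEs, tested at
~1,250 features).

**Isoform-discordance call.**  Within each multi-isoform family, let *c* be
the `SHARED_ISOFORMS` (common) record and S the testable
`ISOFORM_SPECIFIC` records.  The verdict is

* `SPLICING_DISCORDANT` if some s ∈ S has p_s < `p_iso` (default 0.01) and
  |log2fc_s − log2fc_c| ≥ log2 `fc_de`, while *c* is testable but does not
  itself pass the abundance filter;
* `ABUNDANCE_CONCORDANT` if *c* and some s ∈ S both pass the abundance
  filter in the same direction;
* `UNTESTABLE` otherwise, with a reason column separating structural
  failure (no testable common or specific group) from a quiet family.

The divergence term |log2fc_s − log2fc_c| is the isoform-usage contrast:
the specific group must move *relative to the total protein*, not merely in
absolute terms.  A raw significance threshold alone would fire on ~1% of
null specific groups by construction, and a whole-protein shift measured
marginally below the 2-fold filter on the common group would otherwise
masquerade as discordance; anchoring the specific shift to the common shift
removes both failure modes while preserving the intended signature — a flat
common group beside a many-fold specific shift.  The isoform filter is a
raw p threshold by design (not an FDR cut); q-values are reported alongside
for transparency.

**Pooled proportion comparison.**  For count phenotypes (k₁/n₁ vs k₂/n₂), a
2×2 chi-square with 1 df and no continuity correction on the pooled counts;
identical proportions short-circuit to χ² = 0, p = 1.  Percentages are
displayed rounded to the nearest integer.

**PCA QC.**  Centered PCA of samples over complete features (groups
observed in every sample; mean-filling is a config option), with a
separation score = |mean_A − mean_B| on PC1 in units of the pooled
within-cohort SD.

## The synthetic-data generator

The generator is first-class, truth-bearing code: it emulates the data
*structure* of the emulated study so that recovery of planted effects is a
meaningful test of the whole pipeline.

Defaults (the study conditions): 12 vs 11 samples; 1,400 protein families;
10% of families carry 2–3 isoforms; 3–8 peptides per protein of which ~30%
are isoform-specific in multi-isoform families (always at least one common
and one specific peptide per isoform); 2% of peptides duplicated into a
second family (gene-level shared); 369 families with a whole-protein shift
of 2–8-fold (log2-uniform, random sign, applied to cohort B); 6 families
with an isoform-usage shift of 6–50-fold applied *only* to one isoform's
specific peptides, the common peptides receiving a compensatory drift
capped at 1.1-fold; lognormal multiplicative noise with CV 0.3
(σ_log2 = √ln(1+cv²)/ln 2); per-sample loading offsets ~ N(0, 1) on the
log2 scale (removed by median centering); 10% missing-at-random cells.
Baseline protein abundance is N(20, 2) in log2 (areas around 10⁶, a typical
SWATH scale) with per-peptide response factors N(0, 1) in log2.

Protein sequences are synthesised tryptic-friendly — peptide bodies avoid
K/R/P and end in K or R, proteins are concatenations of their peptides — so
digesting the emitted FASTA at zero missed cleavages reproduces the emitted
peptide map exactly (tested).  All outputs are byte-deterministic given the
seed.

What the generator does **not** emulate: intensity-dependent missingness
(real DIA dropout is biased toward low abundance; missing-at-random keeps
recovery tests sharp), correlated peptide noise within a protein,
interference/background in extracted areas, batch or run-order effects, and
retention-time artefacts.  Passing recovery tests therefore demonstrate the
correctness of the pipeline's logic under its own model, not robustness to
every pathology of real acquisitions.

## Numerical and design choices

* Peptides are keyed by (sequence, modification); a modified peptide with
  no exact map entry falls back to the unmodified-sequence entry, so
  digestion-derived maps work with modified exports.
* Accession sets are ordered lexicographically to form stable group ids;
  records sort by p with ties broken by group id; all randomness flows
  through one seeded generator per entry point.
* Unmapped peptides and peptides whose accession set is empty after catalog
  intersection (contaminants, decoys) are excluded and counted in the run
  log, not fatal.
* I/L ambiguity is not collapsed by default (search engines report matched
  sequences); a `collapse_il` switch exists in the digest module.
* Fold-agreement checks in the test-suite compare planted and empirical
  folds on the ratio (natural-log) scale with a band of 3·(cv/√min(n_A,n_B)).
* Problem sizes in the test suite — 1,400-family recovery runs, a
  1,000-family null calibration, 200 planted splice families at CV 0.3, and
  1,000 label permutations — were chosen as the smallest sizes at which the
  binomial error bands of the calibration and recovery checks are
  informative.

## Known limitations

* **Log-of-sum dropout bias.**  A group's area is a sum over observed
  members, so when a dominant member peptide drops out in some samples the
  group's log2 value jumps downward there, biasing cohort fold estimates
  (a 16-fold planted shift can read ~10-fold when the major specific
  peptide is missing in a third of one cohort).  The discordance caller is
  robust to this (the divergence threshold is far smaller than planted
  shifts), but reported fold magnitudes of sparse groups should be read
  with care; fold-accuracy checks in the suite therefore estimate folds
  over samples where the group is completely observed.
* The digestion-derived peptide map approximates a search engine's
  protein grouping; engines merge evidence across databases in ways a pure
  in-silico digest cannot reproduce.
* Only two-cohort designs are supported; no moderated/empirical-Bayes
  shrinkage, no imputation, no batch correction.
* The permutation FDR pools null p-values across features; strongly
  heteroscedastic features could make the pooled null slightly
  conservative or liberal for individual groups.
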