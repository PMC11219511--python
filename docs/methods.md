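# Methods

This note documents the models, procedures and numerical choices behind
`methylrad`, and what the synthetic-data generator does and does not
emulate.

## In-silico FspEI digestion

FspEI is simulated purely at the level of site discovery: the genome's
forward strand is scanned for the four recognition motifs CCGG (CG
context) and CCTGG / CCTGT / CCAGG (CHG context).  Forward-only scanning
of exactly this printed set is deliberate: CCGG is self-complementary and
CCTGG/CCAGG are mutual reverse complements, so the forward scan already
accounts for both strands of the symmetric motifs; the asymmetric CCTGT is
scanned as written.  All overlapping matches are reported — nothing in the
method definition justifies suppression, and an overlap-aware scan is the
definition an independent regular-expression oracle can verify.  `N` in
the genome never matches (conservative: no phantom sites).  The enzyme's
actual methylation dependence and cut-site stagger are not modelled; the
scan enumerates *potential* methylation sites, and observed tag counts
carry the methylation signal.

Tag fragments are the motif plus a symmetric flank (default 14 bp, giving
32-bp tags for the 4-bp motif and 33-bp for the 5-mers — the MethylRAD tag
length scale; the flank is a parameter because fragment geometry varies
between library designs).  The default treats the reference as linear
(matching a linear FASTA) and drops fragments that overrun an end, with a
warning; `circular=True` wraps them around the origin, appropriate for
organellar genomes.

## Site annotation

A site is *genic* when its motif start lies in a gene span, else
*promoter* when within `promoter_len` (default 200 bp) upstream of a
gene's strand-aware start, else *intergenic*; the three labels partition
the sites.  200 bp is a compact-genome convention, not a biological
constant — it is exposed as a flag.  Overlapping genes are resolved
deterministically (first in start-sorted order wins, logged).

## Counting, filtering, normalization

Internally all coordinates are 0-based half-open; GFF3/TSV (1-based
inclusive) and BED (0-based half-open) conversions happen only at the
format boundary.  Tag reads are assigned to the unique fragment they match
on either strand within `max_mismatch` substitutions (default 0); reads
matching zero or ≥ 2 fragments are discarded and tallied.  This exact
matcher replaces a short-read aligner for synthetic tags; real libraries
can instead be aligned externally and imported from SAM/BAM with the
MAPQ ≥ 10 filter (the conventional threshold that removes multi-mapping
placements).

Sites are retained when at least one library covers them with more than
two reads.  RPM is `count × 10⁶ / library_total`; library totals default
to the count-table column sums (the only total available when importing a
table) and can be overridden from a totals file.  A site counts as
*methylated* in a sample when its raw count is ≥ 1 after the global
filter — the laxest defensible presence rule; deeper per-sample thresholds
are a flag (`min_reads`) because published summaries rarely state one.
The methylation level of a context is 100 × methylated / potential sites.

## Differential methylation

The count model is the standard RNA-seq-style negative binomial:
K_ij ~ NB(μ_ij, α_i), μ_ij = s_j q_ig, Var = μ + αμ².

- **Size factors** are median-of-ratios over sites with nonzero counts in
  every sample; when no such site exists the estimator falls back to
  library-size ratios scaled to geometric mean 1 (warned).
- **Dispersion** is estimated per site by method of moments on normalized
  counts with the group structure removed, then a log-linear
  mean-dispersion trend is fitted across sites, and each per-site estimate
  is shrunk halfway toward the trend in log space (sites with non-positive
  moment estimates take the trend value).  Floor 10⁻⁸, cap 10, for
  stability on tiny matrices.  This is a deliberately compact version of
  the empirical-Bayes machinery of the large RNA-seq packages: no outlier
  replacement, no independent filtering, no numeric identity with them —
  the operating characteristics (type-I error, FDR control, power) are the
  design target, and the acceptance checks measure exactly those.
- **Testing**: a log-link NB GLM with the group indicator and log-size-
  factor offset is fitted per site (statsmodels); the Wald statistic on
  the group coefficient is referred to a t distribution with n₁+n₂−2
  degrees of freedom — a small-sample correction appropriate for the 4–20
  samples per group this package targets.  All-zero sites get NA p-values
  and are excluded from the Benjamini–Hochberg denominator; significance
  is fixed at p_adj < 0.05.  The full study-style contrast grid (origin
  within all/field/lab, cultivation within all/origin, temperature pairs,
  origin at each temperature) is expressed through the single two-group
  interface plus sample subsetting (`standard_contrasts()`), and the CLI
  reproduces each by name.

Measured on the synthetic conditions (200 sites, 6 vs 6, NB mean 50):
null raw-p rejection at the 0.05 level is ≈ 0.045 (4000 tests), the BH
false-discovery proportion is ≈ 0, and planted 4-fold changes at
dispersion 0.05 are recovered with ≈ 100% power — these numbers are
recomputed, not quoted, by `scripts/acceptance.py` and the test suite.

GO enrichment is the classic one-sided Fisher exact test per term
(in/out-foreground × has/hasn't-term), BH-adjusted across terms, with the
gene→GO map supplied by the user; the weighted-graph style enrichment
algorithms are out of scope.

## Multivariate analysis

PCA centers (and by default unit-scales) the site variables and takes the
thin SVD of the sample × site matrix; zero-variance sites are dropped
first.  Signs are fixed by making each component's largest-magnitude
loading positive, so results are fully deterministic.  Outlier flagging is
a transparent centroid-distance rule — flag samples beyond
mean + 3 SD of all centroid distances, re-evaluate once after removal —
standing in for opaque package-specific criteria; it is seeded-testable
and its two parameters are visible.

Epigenetic distances are Euclidean distances in the *full* PCA score
space.  With all components retained and no unit scaling this equals the
distance on the centered data matrix itself (rotation invariance, asserted
numerically in the tests); retaining all components avoids an arbitrary
component cut-off.  Within-group distance lists are compared with a
Shapiro–Wilk normality report per group and a two-sided Wilcoxon rank-sum
test — exact enumeration for group sizes ≤ 50, normal approximation with
tie correction beyond.  Note the C(n,2) within-group distances are not
independent observations; as in common practice the rank-sum p-value is
reported on them regardless, and should be read descriptively.

The Mantel test correlates the upper triangles of two distance matrices
(Pearson) and permutes the rows/columns of the second jointly with a
seeded generator; p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1), one-sided
for positive association by default (the commonly reported direction;
'less' and 'two-sided' are available).  When n! ≤ n_perm + 1 the full
permutation group is enumerated instead and the p-value is exact.
Constant matrices are rejected rather than returning an undefined r.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of a two-origin kelp
common-garden methylome study: a ~130-kb circular genome carrying exactly
the reference motif census (69 CCGG, 61 CCTGG, 77 CCTGT, 63 CCAGG = 270
sites, 69 CG / 201 CHG) — every accidental motif occurrence in the random
background is destroyed by single-base substitution and the requested
occurrences planted at non-overlapping positions (≥ 5-base gaps, so no
accidental match can bridge two planted sites), with a re-scan verifying
exact counts before return; ~139 non-overlapping genes covering ~60% of
the genome; and a 41-sample design (2 origins × 10 field samples + 21 lab
samples at 5/10/15 °C).

Methylome counts follow the NB model the test assumes (Var = μ + αμ²,
default dispersion 0.1, mean depth 50, lognormal library-size variation
with SD 0.3 on the log scale).  Site-level methylation occupancy is
context-specific (defaults 0.21 for CG, 0.25 for CHG, the level scale of
an organellar MethylRAD screen); capability is shared between groups for
most sites, with a 10% divergence fraction redrawn independently per group
(group-specific presence/absence methylation, marginal occupancy
unchanged).  That shared-majority structure matters: it keeps the
all-nonzero site set dominated by non-differential sites, which is what
makes median-of-ratios normalization identifiable — a generator whose
groups share no sites would let the size factors absorb the planted fold
changes, as real designs would too.  Differential sites are drawn from the
sites capable in every group and have their mean multiplied by 2^lfc
(default 4×) in the designated group.  Reads are exact fragment copies on
a random strand with optional per-base substitution errors; at error rate
0 the counter recovers the count matrix exactly.  At a per-base error rate
of 0.01 on 32-bp tags, binomial arithmetic caps single-mismatch recovery
near 96% of reads (P[≤ 1 error] ≈ 0.959), and the tests assert
accordingly: essentially no misassignment, and recovery at or above that
scale.

Not emulated: bisulfite chemistry, enzyme efficiency and dosage effects,
mapping ambiguity beyond substitutions, batch effects, genetic variation
between origins, and any correlation structure among neighbouring sites.
Passing tests therefore demonstrate that the pipeline's *computations* are
correct and well-calibrated under the stated model — not that the model
captures every property of real MethylRAD libraries.

## Problem sizes

The test suite and acceptance script run the digestion census on a 130-kb
genome, the end-to-end chain on the full 41-sample design (~185k reads),
and the differential-test calibration on 20 null + 20 power datasets of
200 sites × 12 samples each — sizes at which every check completes in
seconds on a single CPU while keeping the Monte-Carlo error of the
calibration estimates (binomial SE ≈ 0.003 at 4000 tests) well inside the
asserted bands.

## Known limitations

- The NB Wald test is not numerically identical to any released RNA-seq
  package; only its operating characteristics are guaranteed.
- The promoter definition (200 bp upstream) and the per-sample presence
  threshold (≥ 1 read) are conventions, surfaced as flags.
- Wilcoxon p-values on pairwise-distance lists inherit the usual
  non-independence caveat.
- The exact tag matcher assumes tags are unique in the reference; repeats
  would be discarded as ambiguous rather than probabilistically assigned.
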