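# Methods

## Scoring model

A position frequency matrix (PFM) of base counts `c_i(b)` over columns
`i = 1..L` is converted to a log-odds position weight matrix against a
background distribution `q` with a pseudocount mass `p` distributed in
proportion to the background:

```
w_i(b) = log2( (c_i(b) + p·q_b) / ((N_i + p) · q_b) )
```

with `N_i` the column-i count total. Defaults are `p = 0.8` and uniform
background (`q_b = 0.25`), the common JASPAR-ecosystem convention; both
are exposed as parameters because published web-tool scores can differ
from local ones by the exact pseudocount convention used. Raw scores
are in bits (log base 2); a 15-column nuclear-receptor matrix then
yields consensus scores in the low teens, the familiar scale for
DR3-type element predictions.

Scanning scores every length-L window on both strands (the reverse
strand via the weight matrix flipped in both axes, which equals scoring
the reverse-complemented window) and filters on the min-max relative
score `100·(S − Smin)/(Smax − Smin)`. Relative scores are clipped to
[0, 100] to absorb float rounding at the range boundaries. Windows
containing non-ACGT characters are skipped and counted in a log line
rather than given fabricated scores. Coordinates are 0-based half-open
internally; all written output is 1-based inclusive.

The default working threshold for `scan()` is 70% with 80% as the
stricter preset. The *fixture* inventory threshold is 80% (see below).

## Variant coordinates

The supported dialect anchors negative offsets to coding positions:
`c.1-N` (equivalently standard `c.-N`) is N bp upstream of the
translation-start A; `c.<k>-N` is N bp upstream of the first base of
the exon whose first coding position is k (so with a 41-bp first exon,
`c.42-N` addresses intron 1). The anchor position is derived from the
user-supplied exon table, never hard-coded. Supported operations: SNV,
duplication (the copy inserted 3' of the duplicated interval, the
usual convention), deletion, and insertion after the anchor base.
Stated reference bases are verified against the mapped interval at
application time; mismatches raise an error quoting expected vs found.

## Impact assessment

For each variant, both alleles are scanned unthresholded over a window
extending `pad` bases beyond the variant locus (default
`L − 1 + locus length + |length change|`, the smallest pad whose result
is provably invariant to further enlargement — property-tested). The
best-scoring hit overlapping the locus is selected per allele (ties:
smaller start, then forward strand); the percent change
`100·(S_wt − S_mut)/S_wt` is reported on the raw log-odds scale, with
the min-max-relative version reported alongside because published
"percent reduced" values do not state their scale. When the wild-type
best raw score is ≤ 0 the raw-scale percentage is undefined and
reported as missing. For insertions/duplications the mutant locus is
widened by the inserted length so shifted copies still count as
overlapping. Categories: `creates/duplicates` when the mutant allele
has strictly more thresholded hits over the locus than the wild type;
otherwise `disrupts` when the best overlapping score drops; `none` when
no thresholded hit overlaps the locus in either allele (then the
percent change is reported as 0 — there is no element whose change is
meaningful).

## Cohort statistics

MAF is `(het + 2·hom)/(2n)` under listwise deletion of missing
genotypes. The Hardy–Weinberg test is the exact conditional test
(probabilities of all heterozygote counts compatible with the observed
allele counts; p = sum of those ≤ the observed one), computed with
log-gamma arithmetic and unit-tested against exact rational
enumeration. The dominant-model comparison (carriers, genotype > 0, vs
non-carriers) returns both the pooled-variance and Welch t-tests;
summary-statistic versions reproduce the raw-data versions exactly.
"Adjusted t-test" is implemented as ordinary least squares
`antifxa ~ carrier + covariates` — the only standard way to adjust a
two-group mean comparison — with sex dummy-coded and rs2227589 entered
as a carrier indicator, mirroring the tested variant's coding. With an
empty covariate list the OLS carrier contrast reproduces the pooled t
p-value to 1e-9 (tested). Rank-deficient designs raise an error naming
the dependent columns. `mean_ci` uses the normal quantile by default
(which reproduces quoted reference-pool intervals such as
97.1 ± 6.6 → [95.8, 98.4] at n = 100); a t-quantile option exists.

## Expression quantification

Relative expression is `2^−ΔCT` against a same-sample reference gene;
replicates are aggregated by geometric mean (arithmetic mean of ΔCT),
the natural average for an exponential quantity. Fold change is the
ratio of geometric means — identical to `2^−ΔΔCT` for single
replicates — with sd by first-order propagation of the log2 replicate
spread. Dose dependence is tested by least-squares regression of log2
relative expression on numeric dose (0/40/80/106 ng/ml); the log scale
matches fold-change semantics. Dose units are ng/ml throughout. At
least 3 distinct doses are required for the trend test.

## Synthetic data

The generators encode the study conditions; their defaults are fixed,
not tuning knobs.

* **Matrix** — fixtures score against a synthetic DR3-style matrix
  (`SYN_DR3`): two direct-repeat RGGTCA/RGTTCA hexamer half-sites
  spaced by 3 bp, 15 columns, depth 100, with informative half-site
  columns and near-uniform spacer columns. It is a stand-in with the
  family's typical shape and information content, not a database entry;
  analyses of a real gene take the user's matrix file.
* **Background** — i.i.d. bases at GC fraction 0.40, typical of the
  AT-rich non-coding context of the modelled locus.
* **Planting** — a motif instance at a target relative score is built
  deterministically from the consensus by greedy single-base
  substitutions that approach the target without overshooting below
  `target − tolerance`; unreachable targets raise an error reporting
  the closest achievable score.
* **Gene fixture** — geometry: 1,500 bp promoter, exons of 41/150/150
  bp, introns of 2,000/1,000 bp (small enough for sub-second scans,
  shaped like the sequenced regions of interest). Five elements are
  planted — promoter at relative scores 85/88, intron 1 at 96/84,
  intron 2 at 86 — and five variants are composed against the realised
  sequence: a far-upstream SNV off any element, a promoter SNV inside
  an element (alt base chosen as the most damaging), a 4-bp duplication
  inside the strongest intron-1 element, a 20-bp duplication containing
  the second intron-1 element whole, and an SNV at the strongest
  element's 3' edge. The background is redrawn (rejection sampling over
  sub-seeds) until the scan recovers exactly the planted sites and
  every variant shows its intended category, so the truth record is
  exact by construction for any seed; the accepted attempt index is
  recorded in the truth record. Acceptance of ~50–60% per draw at the
  80% threshold makes this converge in a handful of attempts.
* **Fixture threshold** — 80%, the stricter of the two conventional
  presets. On a min-max relative scale, any realistically informative
  15-column matrix scores random background windows above 70% at a few
  per kilobase-pair-scale contig, so a clean five-element inventory is
  a property of the 80% tier; the 70% default of `scan()` itself is
  unchanged.
* **Cohort** — genotypes `Binomial(2, MAF)` (Hardy–Weinberg); phenotype
  `baseline + effect·carrier + covariates + N(0, σ)`. Defaults mirror
  the modelled control cohort: n = 307, MAF 0.013 (expected ≈ 7.9
  carriers), baseline 96.4%, carrier effect −5.7 percentage points,
  noise sd 7.0 (between the two group sds typically reported), age
  ~N(43, 12) truncated to [18, 85], 55% female, rs2227589 at MAF 0.10
  with modest covariate effects (−0.05 %/yr age, +1.0 female, −1.5
  rs carrier). These covariate effects are plausible magnitudes for
  antithrombin activity, chosen once; nothing downstream depends on
  their exact values.
* **qPCR** — reference-gene CT constant (17.0); target CT =
  `base_CT − log2(fold(dose)) + N(0, σ)` with base CTs 24 (SERPINC1)
  and 26 (VDR), σ = 0.15 cycles, 6 replicates per dose. Default fold
  maps interpolate geometrically from 1 at dose 0 to 1.5-fold
  (SERPINC1) and 2-fold (VDR) at 106 ng/ml, the modelled cell-line
  responses. At zero noise the pipeline recovers the planted folds
  exactly (tested).

What the generators do *not* emulate: linkage structure between
variants, genotyping error, non-Gaussian phenotype tails, plate/batch
effects, or amplification-efficiency differences between genes. Tests
passing on this synthetic data therefore demonstrate correctness of the
computations under the stated model, not robustness to those real-data
features.

## Pipeline

`run_study` executes inclusion bookkeeping → gene scan + impacts →
cohort statistics → expression, each stage timed and logged; a missing
or disabled section is marked `skipped`, and a stage failure aborts
with the stage name after writing the partial report. Report JSON has
sorted keys and floats rounded to 6 significant digits so repeated runs
are byte-identical (tested); provenance records the package version,
seed, config hash and input-file digests.

Example `study.yaml`:

```yaml
seed: 1
inclusion:
  recruited: 158
  exclusions: {coding-region defect: 127, hypoglycosylation: 8}
gene:       {source: simulate, threshold: 80}
cohort:     {source: simulate, n: 307, maf: 0.013, effect: -5.7}
expression: {source: simulate, replicates: 6}
```

File-based runs replace `source: simulate` with paths
(`matrix`/`fasta`/`genemodel`/`variants` for the gene stage, `file` for
cohort and expression).

## Problem sizes and numerical choices

The bundled test suite and acceptance script run on one CPU in a few
minutes total. Simulation counts were sized for stable estimates at
that scale: 10,000 null cohorts for type-I-error calibration (binomial
sd of the rejection rate ≈ 0.002 at α = 0.05), 1,000 plates for the
fold-change recovery (Monte-Carlo se ≈ 0.002), 200 random
matrix/sequence pairs for scanner-oracle identity. Scanner/oracle
agreement is asserted to 1e-9 absolute in bits; OLS-vs-t equivalence to
1e-9 in p; exact-test agreement with rational enumeration to 1e-9
relative. Ties in consensus calls break alphabetically; ties in
best-hit selection break toward smaller start, then forward strand.

## Known limitations

* Single-matrix engine: no multi-matrix databases, higher-order
  backgrounds, or de-novo motif discovery.
* The variant grammar covers SNV/dup/del/ins in the upstream/intronic
  dialect only — no full HGVS (no p./g./r., no delins), no transcript
  databases; reverse-strand gene models are accepted but only
  forward-strand models are exercised by fixtures.
* Published web-tool scores may differ from locally computed ones by
  the (unknown) pseudocount/background the tool used; both the raw and
  relative percent-change scales are reported for this reason.
* No haplotype modelling, no binding thermodynamics, no
  amplification-efficiency calibration.
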