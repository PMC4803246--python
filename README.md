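# vdrescan

Regulatory-variant analysis for vitamin D response elements (VDREs) in a
single gene, built around the kind of study that asks: *do non-coding
variants in the promoter or introns of an anticoagulant gene disturb the
DNA elements through which the vitamin D receptor regulates it, and do
carriers of such variants have lower plasma activity?*

The package bundles the four computational stages such a study needs,
plus a seeded synthetic-data generator so every stage is testable with
no downloads:

1. **Motif scanning** (`vdrescan.motif`) — build a log2-odds position
   weight matrix (PWM) from a JASPAR-style count matrix and scan DNA on
   both strands. A window of length *L* scores
   `S = Σᵢ log2((cᵢ(b) + p·qᵦ) / ((Nᵢ + p)·qᵦ))`, where `cᵢ(b)` is the base
   count in column *i*, `Nᵢ` the column total, `qᵦ` the background
   probability and `p` a pseudocount. Hits are reported on the min-max
   relative scale `100·(S − Smin)/(Smax − Smin)` so thresholds such as
   70% or 80% are matrix-independent.
2. **Variant anchoring** (`vdrescan.genemodel`) — parse the clinical
   coordinate dialect used for upstream and intronic variants
   (`c.1-1053C>T` = 1053 bp upstream of the ATG; `c.42-1060_-1057dupTTGA`
   = a 4-bp duplication 1057–1060 bp upstream of the first base of
   exon 2, inside intron 1), map it onto a reference contig through an
   exon table, and build mutant alleles.
3. **Impact scoring** (`vdrescan.impact`) — rescan wild-type and mutant
   alleles around each variant, pick the best-scoring hit overlapping
   the locus on each allele and report the percent score reduction;
   variants are classified `disrupts`, `creates/duplicates` (e.g. a
   duplication that copies a whole element) or `none`.
4. **Cohort and expression statistics** (`vdrescan.cohort`,
   `vdrescan.qpcr`) — minor allele frequency, exact Hardy–Weinberg test,
   dominant-model t-tests (pooled and Welch), covariate-adjusted linear
   association (age, sex, rs2227589), summary-statistic inference, and
   comparative-CT (2^−ΔΔCT) quantification of qPCR dose-response with a
   log2-scale trend test.

`vdrescan.simulate` generates the inputs these stages consume —
background DNA with motif instances planted at controlled relative
scores, a study-shaped gene fixture with five planted elements and
variants of known consequence, Hardy–Weinberg cohorts with a planted
carrier effect, and qPCR plates with planted fold changes — each with a
machine-readable truth record. `vdrescan.pipeline` orchestrates all
stages into one deterministic JSON report.

## Worked example

Generate the default synthetic gene fixture and run the full study:

```sh
vdrescan simulate gene --seed 1 --out fixture
vdrescan run --config study.yaml --out out   # config as in docs/methods.md
```

The fixture plants five DR3-type elements (two promoter, two intron 1,
one intron 2) and composes five variants against the realised sequence.
Scanning at the 80% relative-score threshold recovers exactly the
planted inventory:

```
sequence_id  start  end   strand  site             raw_score  relative_score
SYNGENE1     1286   1300  -       GAGTCAACGGGTTTA  12.837     85.2
SYNGENE1     1319   1333  -       AAGTCAACGGGTTCA  14.724     88.8
SYNGENE1     2451   2465  +       CAGTCAACGGGTTCA  12.186     84.0
SYNGENE1     2472   2486  -       GGGTCAACGCGTTCA  17.967     95.0
SYNGENE1     4101   4115  +       GAGTCAACGCGTTCA  13.134     85.8
```

and the impact table classifies each variant (percent change of the
best overlapping raw score, positive = reduction):

```
variant                 category            pct_change_raw
c.1-1053T>A             none                0
c.1-171A>C              disrupts            32.8
c.42-1060_-1057dupGACC  disrupts            19.7
c.42-1091_-1072dup      creates/duplicates  0
c.42-1056C>A            disrupts            19.7
```

The far-upstream SNV touches no element; the promoter SNV and the 4-bp
intron-1 duplication each disturb one of the five elements; the 20-bp
duplication copies a whole element (two thresholded hits over the locus
in the mutant allele versus one in the wild type); the intron-1 SNV
clips the 3' edge of the strongest element. The same report carries the
cohort section (for the seed above: MAF 0.0081 with 5 heterozygous
carriers out of 307, Hardy–Weinberg p = 1.0, carrier vs non-carrier
anti-FXa 91.0% vs 96.8%) and the expression section (SERPINC1 1.58-fold
and VDR 2.18-fold at the 106 ng/ml dose for this plate realisation,
dose-trend p < 1e-8).

Library use mirrors the CLI:

```python
from vdrescan import simulate_gene_fixture, study_report, parse_cvariant

fx = simulate_gene_fixture(seed=1)
tables = study_report(
    fx.pwm, fx.sequence, fx.model,
    [parse_cvariant(v) for v in fx.variants],
    threshold=fx.truth["threshold"],
)
print(tables.inventory)   # five planted elements
print(tables.impacts)     # one classified row per variant
```

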