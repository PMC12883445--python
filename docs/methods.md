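# Methods

## Statistics

### Xhet

For one sample, over variant records inside the shared non-PAR interval of
chromosome X (`chrX:2,781,479–153,925,834`, valid as printed for GRCh37,
GRCh38 and T2T because it is the smallest interval excluding PAR1/PAR2
common to all three; both bounds inclusive, matching region-string
semantics), calls are kept when they pass the parametric filters and
classify as heterozygous or homozygous-alternate. Then

    Xhet = n_het / (n_het + n_homalt).

Hom-ref genotypes are excluded from the denominator: the statistic is the
het proportion among *variant* genotypes, which is what a carrier-
ascertained single-sample VCF exposes anyway. On hemizygous (XY) non-PAR X
true heterozygosity is impossible, so Xhet ≈ 0 up to artifacts; for XX
samples the expectation under Hardy–Weinberg with site alt frequencies
p_i is

    E[Xhet] ≈ Σ 2 p_i (1 − p_i) / Σ (2 p_i (1 − p_i) + p_i²),

about 0.78 under the simulator's default Uniform(0.05, 0.5) frequency
spectrum. The exact value observed on real data depends on caller
ascertainment and the cohort's frequency spectrum; only the bimodal
separation, not the absolute level, is used for inference.

Genotype-class rules: any missing allele (including half-calls `./1`)
classifies as missing — conservative, and half-calls are too rare to fix a
convention around; haploid calls map `0` → hom-ref, any alt → hom-alt; any
two distinct diploid alleles (e.g. `1/2`) are het, identical non-ref
alleles hom-alt; multiallelic records are keyed by their full alt set and
never split. The phasing separator is ignored. An undefined Xhet (no
qualifying genotype) is reported as missing alongside its counts, never
coerced to 0, so degenerate samples cannot be silently mis-clustered.

### Filters

Thresholds implement the printed inequalities exactly: allele fraction
strictly > `af_min` (default 0.25), depth strictly > `dp_min` (default
20), genotype quality ≥ `gq_min` (optional; direction chosen as the
conventional "at least this confident"), and sites with strictly more
than `miss_max` (default 20%) missing genotypes are excluded after
merging. The allele fraction of a call is the AD-derived fraction of all
non-reference reads; when AD is absent a caller-supplied VAF/AF FORMAT
value is used, and when neither exists the call *passes* AF/DP filters by
default (permissive mode) because genotype-only VCFs would otherwise lose
every call — `--strict-filters` inverts that. VAF windows used by the het
scan (25–75, 33–66, 45–55 percent) are inclusive on both ends.

### KING-robust kinship

For each pair, over jointly non-missing sites,

    phi = (N_Aa,Aa − 2 N_AA,aa) / (N_Aa,i + N_Aa,j),

the symmetric-denominator form of the robust within/between-family
estimator (the form standard VCF toolchains report). Degrees use the
powers-of-two convention: phi > 0.354 duplicate/MZ, (0.177, 0.354] first,
(0.0884, 0.177] second, (0.0442, 0.0884] third, else unrelated; a zero
denominator yields an explicit `undefined`, never 0. All contigs are used
by default with an `--autosomes-only` switch; hemizygous male X genotypes
(coded hom) depress het counts and inflate opposite-homozygote counts,
so autosomes-only is recommended whenever X sites are a large fraction of
the input.

**Ascertainment bias of the standard pre-filter.** The composite `qc`
pipeline applies the AF/DP pre-filter per call, merges, then applies the
missingness rule. On small cohorts this retains mostly sites where every
sample carries the variant; with opposite-homozygote evidence removed,
phi is biased upward for *all* pairs (unrelated pairs can reach 0.2–0.35
depending on the frequency spectrum). The ranking — self > parent-child >
unrelated — is preserved, which is what the QC screen uses. When
genotype-complete multi-sample data are available, disabling the AF/DP
filter (negative flag values) recovers the theoretical ladder
(0.5 / 0.25 / 0.125 / 0 within ±0.02 at 20k sites in validation).

### Sex-group inference

Unsupervised mode: deterministic 1-D 2-means over the defined Xhet values
(centers initialized at the min and max, ties to the lower cluster),
cutoff at the midpoint of the two final cluster means; identical values
raise a "no separation" error. Classification: below the cutoff →
`xy-like`, at/above → `xx-like`, within a margin (default 10% of the
cutoff — conservative, exposed as `--margin`) → `ambiguous`. Labels are
deliberately genotype-pattern terms, not sex terms: aneuploidies (XXY,
X0), mosaicism and consanguinity-driven runs of homozygosity shift Xhet
without changing chromosomal sex, and the tool only ever flags.

Supervised mode fits a one-feature logistic regression by IRLS. Clean
cohorts are perfectly separated, where the unpenalized MLE does not exist;
divergence is detected (non-convergence / exploding coefficients) and a
small ridge penalty (1e-3) re-stabilizes the fit, which is reported with a
`separated` flag. Coefficients under separation are therefore
penalty-dependent and only the decision boundary is meaningful.

### Pseudo-heterozygosity scan

Restricted to exonic SNVs of a caller-declared hemizygous-expected sample
set, a call qualifies when it classifies het and its allele fraction lies
in the window. Two tallies are kept distinct because both phrasings are
used in practice: *unique het positions* (site keys with ≥1 qualifying
call) and *het genotype calls* (sample-summed). Gene and region
aggregation assigns a call to every overlapping interval — overlapping
gene pairs are each credited in full — and region densities are
calls / (span in Mb), with nested regions tallied independently. Inputs
lacking AD are rejected here (a VAF window is meaningless without a
fraction). Exon/gene/region intervals are always BED inputs, never
fetched; the shipped `chrx_regions_synthetic.bed` is an approximate
synthetic example annotation, not a curated reference.

## The simulator

`simulate` emulates the data regime the QC method targets: founders drawn
under Hardy–Weinberg from per-site alt frequencies (default
Uniform(0.05, 0.5)); offspring by Mendelian transmission; autosomes and
PAR diploid in everyone; non-PAR X — mothers transmit one allele, fathers
transmit their single allele to XX offspring only, XY offspring draw their
X from the mother; male non-PAR X emitted as haploid `1` by default with a
`diploid-male-x` switch emitting `1/1` (both caller conventions occur in
the wild, and both paths are tested). Depth is Poisson (default mean 40,
typical exome coverage), alt allele depth Binomial(DP, p) with p set by
dosage and a 1% per-read miscall floor, GQ a capped linear function of
depth. Injectors: per-call genotype-class flips (default 1e-3), column
swaps, read-mixture contamination, and pseudo-het injection that renders
male non-PAR X sites het with AF ~ Normal(0.5, 0.08) truncated to (0,1) —
concentrated inside labelled trap intervals when any are configured,
genome-wide otherwise — mimicking the mis-mapping signature of paralogous
and pseudogene-rich regions. A run-of-homozygosity injector collapses a
sample's het calls in an interval to homozygotes (alt with probability
equal to the site frequency), emulating consanguinity. One documented RNG
seeded from the config drives everything; identical configs produce
byte-identical VCFs.

What the simulator does **not** model: linkage disequilibrium, population
structure, caller ascertainment of single-sample VCFs, indels/structural
variants, read-level artifacts beyond the binomial AD model. Passing tests
therefore demonstrate correctness of the statistics and their documented
behavior under idealized genotypes, not caller-specific Xhet levels on
real data.

## Validation scales and the documented toy fixture

Validation runs at desk scale, chosen so the full suite completes in
minutes: kinship-ladder recovery at 20,000 autosomal sites (MC noise on
phi ≈ 0.005, comfortably inside the ±0.02/±0.03 assertion bands), sex
separation on 20 samples × 1,000 non-PAR X sites, the het scan on 8 males
× 2,000 sites, exact brute-force equivalence on 100 random 5 × 200
matrices with 10% missingness.

The hand-checkable fixture (`src/xhetkin/data/toy12.vcf`, single sample
`TOY1`, twelve chrX records) exercises every boundary:

| pos | GT | AD | DP | outcome under defaults |
|---|---|---|---|---|
| 2,781,478 | 0/1 | 15,15 | 30 | outside non-PAR (one below lower bound) |
| 2,781,479 | 0/1 | 15,15 | 30 | **het** (inclusive lower bound) |
| 5,000,000 | 0/1 | 30,10 | 40 | AF = 0.25 fails strict > 0.25 |
| 5,000,100 | 0/1 | 37,13 | 50 | **het** (AF 0.26) |
| 5,000,200 | 0/1 | 10,10 | 20 | DP = 20 fails strict > 20 |
| 5,000,300 | 0/1 | 10,11 | 21 | **het** (DP 21) |
| 6,000,000 | 0/0 | 30,0 | 30 | hom-ref, never counted |
| 6,000,100 | ./. | — | — | missing, never counted |
| 7,000,000 | 1/1 | 0,30 | 30 | **hom-alt** |
| 7,000,100 | 1 | 0,25 | 25 | **hom-alt** (haploid) |
| 153,925,834 | 1/1 | 1,29 | 30 | **hom-alt** (inclusive upper bound) |
| 153,925,835 | 0/1 | 15,15 | 30 | outside non-PAR (one above upper bound) |

Hand count: n_het = 3, n_homalt = 3, Xhet = 0.5.

## Known limitations

- Same-sex first-degree pairs (mother–daughter, father–son) are
  indistinguishable: degree and inferred sex group coincide. The output
  states the degree and leaves resolution to orthogonal evidence.
- Kinship here performs no Mendelian-consistency checking and must not be
  used as de novo evidence.
- Xhet cannot distinguish XXY/X0 and similar karyotypes from technical
  artifacts; such samples surface only as `ambiguous` or via coverage
  methods out of scope here.
- The multiallelic het policy (any two distinct alleles) and the
  half-call-as-missing policy are conventions; alternative toolchains may
  split or re-normalize multiallelics and will count slightly differently.
- The three "alternative filter settings" used in the robustness test
  (defaults; + GQ ≥ 20; AF > 0.35 with DP > 30) probe the allele-fraction,
  depth and quality dimensions the tool exposes; they are this package's
  choice of representative settings.
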