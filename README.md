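# xhetkin

Genotype-only sample QC for sequencing cohorts: sex inference from
X-chromosome heterozygosity and pairwise relatedness screening, computed
directly from VCF files — no alignment data required.

## The problem

Two of the most common sample-level failures in sequencing studies are sex
label errors and sample mix-ups, including pedigree inconsistencies in trio
designs. Both leave clear fingerprints in the genotypes themselves:

- **Xhet.** On the non-pseudoautosomal part of chromosome X
  (`chrX:2,781,479–153,925,834`, the smallest interval excluding PAR1 and
  PAR2 shared by GRCh37, GRCh38 and T2T) XY samples are hemizygous, so true
  heterozygous calls are impossible there. After restricting to `0/1` and
  `1/1` genotypes that pass parametric filters (allele fraction > 0.25,
  depth > 20 by default), the per-sample statistic

      Xhet = n_het / (n_het + n_homalt)

  sits near 0 for XY-like samples and substantially above it for XX-like
  samples, giving a clean bimodal separation.

- **KING-robust kinship.** For each sample pair, over jointly observed
  sites,

      phi = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa,i + N_Aa,j)

  where N_Aa,Aa counts shared heterozygotes and N_AA,aa opposite
  homozygotes. phi is ≈0.5 for duplicates/MZ twins, ≈0.25 for first-degree
  pairs, ≈0.125 for second-degree, ≈0 for unrelated — without needing
  allele frequencies or alignment data.

`xhetkin` computes both, clusters samples into `xx-like` / `xy-like` /
`ambiguous` groups (unsupervised 2-means threshold or supervised logistic
fit), flags sex-vs-metadata and pedigree-vs-kinship inconsistencies, and
can scan hemizygous-expected (male) samples for recurrent
*pseudo-heterozygosity* — artifactual het calls caused by reads mis-mapped
from paralogs and processed pseudogenes — under inclusive variant-allele-
fraction windows (25–75, 33–66, 45–55 percent). A built-in simulator
generates pedigree cohorts with ground truth for testing and validation.

## Worked example

Simulate a trio and run the composite QC pipeline:

```sh
xhetkin simulate --out-prefix demo/trio --seed 1
xhetkin qc demo/trio.vcf --outdir demo/qc \
    --sexes demo/trio.sexes.tsv --pedigree demo/trio.pedigree.tsv
```

which prints

```
QC complete: 3 samples, 0 flagged; outputs in demo/qc
```

and writes `xhet.tsv`, `sexinfer.tsv`, `kinship.tsv`, a combined
`summary.tsv`, MultiQC custom-content tables under `multiqc/`, and a
`manifest.json` recording every parameter. The summary for this run:

```
sample	xhet	sex_label	top_kinship_partners	flags
child	0.000000	xy-like	father:0.3648;mother:0.3418	.
father	0.000000	xy-like	child:0.3648;mother:0.3534	.
mother	0.777778	xx-like	father:0.3534;child:0.3418	.
```

The mother's Xhet is ≈0.78 under the simulator's allele-frequency regime
while father and child are exactly 0 — the hemizygous pattern. The phi
values are elevated relative to the theoretical ladder (parent-offspring
0.25, unrelated 0) because the standard pre-filter keeps only variant
carriers at jointly observed sites, which removes opposite-homozygote
evidence and biases phi upward for everyone; rankings remain informative,
and disabling the pre-filter on genotype-complete data recovers the
unbiased ladder (see `docs/methods.md`):

```sh
xhetkin relatedness demo/trio.vcf --af-min -1 --dp-min -1 \
    --autosomes-only --out demo/kinship.tsv
```

yields parent–offspring phi of 0.264 and 0.258 (first-degree) and 0.044
for the unrelated parents. Swapped or mislabelled samples surface in the
`flags`
column (`sex-mismatch:...`, `pedigree-mismatch:...`); flags are advisory
only and never rename or drop samples. Note that same-sex first-degree
pairs (mother–daughter, father–son) are indistinguishable by design, since
both the kinship degree and the inferred sex group coincide.

Other subcommands: `xhet`, `relatedness`, `sexinfer`, `hetscan` (see
`xhetkin <cmd> --help`); all thresholds are exposed as flags and YAML
config keys.

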