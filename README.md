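# imprintscan

Genome-wide detection of **imprinted**, **heritable** and **random
monoallelic** expression from paired genomic-DNA/cDNA SNP-array allele
signals in family-based cell panels.

Genotyping arrays measure two fluorescence channels per SNP, one per
allele. Hybridizing cDNA alongside genomic DNA turns the array into an
allelic-expression (AE) readout: at a site heterozygous in gDNA, the
cDNA allele ratio estimates the relative transcript abundance of the two
alleles. Run across pedigrees, this separates three very different causes
of monoallelic expression that are conflated in single-sample studies:

* **imprinting** — the overexpressed allele always arrives from the same
  parent, regardless of which allele it is;
* **heritable (cis-genetic) AE** — the imbalance tracks a local regulatory
  variant: it appears exactly in regulatory-SNP heterozygotes and is
  transmitted Mendelianly;
* **random monoallelic expression (RME)** — a clonal, epigenetic silencing
  of one haplotype, independent of parental origin and genotype, prominent
  in immortalized lymphoblastoid lines and partially reversible by
  demethylating agents (5-aza-2'-deoxycytidine, AZA).

## Method

For each measurement the B-allele-style ratio is β = X<sub>raw</sub>/(X<sub>raw</sub>+Y<sub>raw</sub>),
with x = log₁₀(X<sub>raw</sub>+Y<sub>raw</sub>). β drifts with total intensity, so it is
calibrated on gDNA heterozygotes (true allelic fraction 0.5): points with
total intensity above 1,000 are split into 50 intensity bins, the median β
per bin is fit with a quadratic ŷ = a + b₁x + b₂x², and every observation
is corrected as β<sub>norm</sub> = β − ŷ(x) + 0.5. Corrected cDNA ratios
β/(1−β) are clamped into [0.1, 10] (beyond that, indistinguishable from
homozygous signal) and summarized as fold magnitude max(ratio, 1/ratio).

The genome scan reports runs of ≥ 3 consecutive informative SNPs whose
per-child mean magnitude exceeds **2.9-fold** (the −1 SD bound of the mean
overexpression at confirmed imprinted genes: 7.39-fold, +1 SD 11.84) in
≥ 2 children; a moderate band of **2–2.9-fold** feeds the
partial-imprinting screen. Windows merge into loci. Each locus is then:

1. **phased** — deterministic Mendelian trio phasing, with triple
   heterozygotes resolved through the transmitted grandparental haplotype
   in three-generation families — giving the parental origin of the
   overexpressed allele per child;
2. **mapped** — a concordance test over unrelated individuals asks whether
   AE presence (and phase-consistent direction) is predicted by
   heterozygosity at any local SNP; concordance ≥ 0.9 calls the locus
   heritable, overriding any imprinted call;
3. **classified** — all origins paternal → paternally expressed imprinted;
   all maternal → maternally expressed; mixed → RME-consistent.

Treatment analysis calls a locus **AZA-affected** when every informative
sample decreases by at least the 1.25-fold change threshold (the 95th
percentile of fold change between untreated biological replicates) and at
least one sample shows ≥ 2-fold AE untreated. IBD sibling concordance
(same overexpressed haplotype, both > 1.5-fold, in siblings sharing both
parental haplotypes) is tested against treatment response with chi-square
and Fisher exact tests.

A fully seeded synthetic-data generator (`imprintscan.simulate`) produces
pedigrees, Mendelian genotypes and two-channel intensities for loci of
every class, so the entire pipeline is testable without array data.

## Worked example

```bash
$ imprintscan simulate --seed 3 --out panel
wrote panel with 522 SNPs, 39 individuals
$ imprintscan scan --input panel/intensities.tsv --pedigree panel/pedigree.ped \
      --snps panel/snps.tsv --out scan
classified 48 loci
$ head -3 scan.loci.tsv
locus_id        chrom   start   end     classification  mean_magnitude  n_transmissions
chr1:1400000-1422000    chr1    1400000 1422000 inconsistent    8.251   17
chr1:1800000-1818000    chr1    1800000 1818000 inconsistent    7.889   17
```

The panel contains 60 loci of known class (20 imprinted, 6 partial, 10
heritable, 10 RME, 14 biallelic) across 9 trios and one three-generation
family. `inconsistent` loci are extreme AE whose overexpressed allele does
not track one parent — the RME signature; imprinted calls carry the
expressed parent (`imprinted_paternal_expressed` / `..._maternal_...`), and
`heritable` marks loci explained by a local variant. On this default
simulation the truth-scored recovery is ≥ 0.9 sensitivity and precision
for imprinted loci with correct parental origin (see
`tests/test_acceptance.py`).

The bundled AZA reference panel reproduces its curated partition:

```bash
$ imprintscan selftest
affected loci: 26 / 70
partition matches the curated reference
```

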