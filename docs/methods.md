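# Methods

## Signal model and normalization

A two-channel array measurement at one SNP yields raw intensities
(X<sub>raw</sub>, Y<sub>raw</sub>), one per allele. The allelic fraction
estimate is the β ratio X/(X+Y); its sampling behaviour depends on total
intensity T = X+Y, and hybridization chemistry adds a smooth,
intensity-dependent distortion. Genomic-DNA heterozygotes provide a
calibration set with known truth (β = 0.5), so the correction is learned
there and applied to both assays:

1. retain points with T > `intensity_threshold` (default 1,000
   fluorescence units — below this, allele discrimination is unreliable);
2. split the retained log₁₀T range into `n_bins` = 50 bins and take the
   median β per bin;
3. fit the bin medians with a quadratic ŷ = a + b₁x + b₂x² (a quadratic,
   not a line: the distortion bends at low intensity);
4. correct every observation as β<sub>norm</sub> = β − ŷ(x) + 0.5,
   truncated into [0, 1].

After correction the median normalized β in every bin sits at 0.5 (the
acceptance suite checks ±0.01 at n = 50,000).

**Binning.** Bin edges are placed at quantiles of the retained log₁₀T
distribution (equal occupancy), and the regression abscissa is each bin's
median log-intensity. With equal-width bins over a lognormal intensity
distribution, tail bins hold only a handful of points and their median β
has sampling error of several hundredths — larger than the effect being
removed. Equal-occupancy bins make every bin median comparably precise.
Empty bins (possible on small inputs) are dropped, never interpolated; at
least `min_nonempty_bins` = 10 are required to fit.

**Folds and clamping.** β<sub>norm</sub> converts to the allelic ratio
β/(1−β), clamped into [`clamp_low`, `clamp_high`] = [0.1, 10]; β of
exactly 0 or 1 maps to the clamp bounds. Ratios beyond 10-fold are
indistinguishable from homozygous signal on this platform, so the clamp
encodes "monoallelic". The fold magnitude max(ratio, 1/ratio) ≥ 1 is the
quantity all downstream thresholds act on. A site is *informative* when
the gDNA genotype is AB and both assays clear the intensity floor. An
optional switch (`gdna_ratio_correction`, off by default) additionally
divides the cDNA ratio by the matched gDNA ratio per SNP; the default
implements exactly the printed correction formula, with the gDNA call
gating informativeness only.

## Window scan

Candidate regions are maximal runs of at least `min_window_snps` = 3
consecutive informative SNPs in which at least `min_children` = 2
children each show a mean fold magnitude (over their informative SNPs in
the run) beyond the threshold. Two bands are scanned: *extreme* —
strictly greater than `extreme_fold` = 2.9 (the −1 SD bound of the
7.39-fold mean overexpression observed at confirmed imprinted genes,
7.39 − (11.84 − 7.39) = 2.94, applied as 2.9) — and *partial* — within
[2.0, 2.9), inclusive below, exclusive above. Maximality means a
reported window cannot be extended by one SNP in either direction and
still qualify; the scanner is equivalence-tested against a brute-force
enumeration of all contiguous runs.

"Consecutive" means consecutive among informative SNPs — homozygous or
low-signal SNPs carry no allelic information and do not interrupt a run —
but only within `window_gap_bp` = 25 kb: adjacent informative SNPs
farther apart than that break the run. Without this cap, runs would
bridge physically unrelated loci hundreds of kilobases apart whenever the
intervening SNPs happen to be non-informative, chaining distinct
monoallelic loci of a chromosome into one window. The cap keeps windows
at the scale of single transcriptional units. Windows within
`merge_gap_bp` = 25 kb of each other merge into loci (transitive
closure, oracle-tested); the merge gap sits below the smallest printed
inter-locus distances in the reference data.

## Phasing and parental origin

Trio phasing is deterministic Mendelian deduction per site: the child's
genotype must combine one allele from each parent; a unique combination
fixes the phase, a Mendelian impossibility flags the site (excluded
downstream), and the triple heterozygote (all three AB) is ambiguous. In
three-generation families, ambiguous sites are resolved by identifying
which grandparental haplotype the parent transmitted (voted over the
locus' decisive sites, assuming no intra-locus recombination in a single
meiosis — loci here span ≲ 1 Mb, where one-meiosis recombination is
rare) and reading the parent's phased allele off that haplotype. In
plain trios the triple-het is genuinely unresolvable and stays ambiguous;
a nearest-flank label-copy heuristic (`resolve_ambiguous_by_flank`) is
available but off by default in the pipeline, because allele labels do
not track haplotypes and the copy is wrong about half the time.

A child's parental-origin call at a locus is the majority over its sites
with known phase and genuine bias (magnitude ≥ `partial_fold_low` = 2.0);
the bias floor keeps noise-level sites, whose "overexpressed allele" is
arbitrary, out of the vote. All known origins paternal →
`imprinted_paternal_expressed`; all maternal → maternal; mixed →
`inconsistent` (RME-consistent); fewer than `min_children` known origins
→ `non_transmitted`.

The same transmitted-haplotype bookkeeping yields IBD: a sibling pair
shares its paternal haplotype at a locus when both received the same
grandparental haplotype from the father (and analogously maternal).
Pairs with unresolvable grandparental origin are skipped.

## Heritability mapping

The cis-genetic prediction for a candidate regulatory SNP with
high-expression allele H: heterozygotes show AE with the overexpressed
haplotype carrying H; homozygotes show none. For every candidate within
`cis_window_bp` = 500 kb of the locus, the concordance score is the
fraction of unrelated individuals (pedigree founders) matching the
prediction, maximized over the two orientations of H; an individual's AE
status is magnitude ≥ 2.0 over the locus' informative sites. The best
score ≥ `mapping_concordance` = 0.9 (tolerating one discordant
individual in ten) over ≥ `min_mapping_individuals` = 10 individuals
maps the locus; a positive mapping overrides any imprinted call.
Direction is scored only where a phase between candidate and expressed
haplotype is available; in this package the founder's haplotype pair is
partially reconstructed from the alleles it demonstrably transmitted to
its first child (decisive trio sites), which is exact under no
intra-locus recombination. Mapped candidates are additionally checked
for Mendelian transmission: in every informative transmission (≥ 1 het
parent) the child must show AE iff heterozygous at the candidate. This
deterministic concordance test is a documented substitute for the
original population-mapping machinery, which is not public; it is
deliberately pluggable.

## Partial imprinting

Moderate loci (2–2.9-fold) pass four screens: (1) detected in the
partial band in ≥ 2 children; (2) not within `boundary_extension_bp` =
5 kb of a classically imprinted locus (redundant boundary signal);
(3) not heritable by mapping; (4) all known origins agree on one parent
*and* the overexpressed allele label varies across children and sites —
expression must track the transmitting parent, not one fixed allele,
which is the signature of a non-genetic parent-of-origin effect and
excludes unmapped fixed-allele cis effects.

## Treatment analysis

The change threshold is derived from untreated biological controls: the
95th percentile (`control_percentile`) of the symmetric replicate fold
change max(m₁/m₂, m₂/m₁), requiring ≥ 20 pairs; 1.25-fold in the
reference panels. A locus is *AZA-affected* when every informative
sample decreases with untreated/treated ≥ the threshold and at least one
sample has untreated magnitude ≥ `treatment_baseline_fold` = 2.0. This
consistent-decrease rule reproduces the bundled 70-locus two-cell-line
reference panel's curated partition exactly (26 affected / 44 not); the
panel ships in `src/imprintscan/data/aza_reference_panel.tsv` and the
check runs as `imprintscan selftest`.

Time courses flag a *strong response* when the late-timepoint magnitude
halves — on the log scale by default (log m₁₀d ≤ ½ log m₀), since
magnitude is a ratio bounded below by 1 and a linear halving of, say,
1.8-fold would cross into the impossible region; a linear rule
(m₁₀d ≤ m₀/2) is available via `response_scale: linear`. Time
consistency requires m₁₀d ≤ m₅d ≤ m₀. The methyl-pulldown comparison
calls a site changed when |treated − untreated| exceeds
`mbd_sd_multiplier` = 1 standard deviation of the across-site difference
distribution (no replicate count is available, so the SD is across
sites), and summarizes the decreased fraction among changed sites.

## IBD concordance

Informative pairs share both parental haplotypes at the locus (IBD-2:
identical genotype and identical parental origins, so imprinted and
heritable AE must agree). Both siblings > `ibd_fold` = 1.5 toward the
same haplotype → concordant; toward opposite haplotypes, or one biased
and the other ≤ 1.5 ("biallelic" is read as the complement of the stated
1.5-fold rule) → discordant; both ≤ 1.5 → uninformative. The 2×2
association with treatment response reports an uncorrected 1-df
chi-square and a two-sided Fisher exact test side by side — the
reference P-value cannot be unambiguously attributed to one test, so
neither is privileged.

## Synthetic panel

Defaults emulate the reference study design: 9 parent-offspring trios
plus one three-generation family (4 grandparents, 2 parents, 6
children); 60 loci — 10 paternally and 10 maternally imprinted, 6
partial, 10 heritable, 10 RME, 14 biallelic — of 5–12 SNPs at MAF
0.1–0.5, spaced 2 kb within loci and 400 kb between them across 4
chromosomes (far beyond the window and merge gaps, so loci stay
distinct). Founders follow Hardy–Weinberg; children receive one intact
parental haplotype per locus, uniformly at random, recorded as truth.

Expression shares per haplotype: imprinted and RME silence one haplotype
to `silenced_allele_fraction` = 1/9 (8-fold AE, within the clamp and
near the observed 7.4-fold mean); partial loci express the biased parent
at f/(1+f) with f ~ U(2.0, 2.9); heritable loci bias regulatory-SNP
heterozygotes by f ~ U(2.0, 6.0) in phase with the high allele. Total
intensity is lognormal (log₁₀ mean 3.5, SD 0.35, so ~8% of measurements
fall below the 1,000 floor — realistic dropout); observed β is the true
fraction plus the quadratic bias a = −0.42, b₁ = 0.19, b₂ = −0.02
(±0.03 over the observed range, comparable to real intensity drift) plus
Gaussian noise (SD 0.02, chosen so biallelic sites essentially never
reach 2.9-fold), truncated to [0, 1]; channels are reconstructed as
X = Tβ, Y = T(1−β). Noise is placed on β rather than per channel because
β is the quantity the pipeline consumes. Treatment reverts RME silencing
by `treatment_response` = 0.5 of its distance to balance per timepoint
(cumulative 1 − 0.5ᵏ), leaving other classes to noise; the
methyl-pulldown panel reduces 80% of 2,000 sites by 50% plus noise.

All randomness flows from one `numpy.random.default_rng` (PCG64)
generator, so a fixed seed reproduces the panel bit for bit.

**What the generator does not model** — and what passing tests therefore
do not establish about real arrays: probe-level chemistry and
cross-hybridization, batch and plate effects, copy-number variation,
intra-locus recombination, linkage between loci, genotyping error, and
strand ambiguity (antisense transcription is invisible to the assay).
Truth-scored recovery on this generator demonstrates the logic of the
pipeline, not its field performance.

## Numerical choices and edge cases

* Ties at exactly 2.9-fold are excluded from the extreme scan (strict
  inequality, "in excess of"); the partial band is inclusive at 2.0 and
  exclusive at 2.9; the IBD rule is strictly greater than 1.5.
* β outside a fitted curve's intensity range is corrected with the
  nearest-edge value (`BiasCurve.in_range` exposes the flag).
* Mendelian-error sites are excluded from all downstream counts, never
  imputed; missing genotypes are retained in tables but never
  informative.
* Percentiles use linear interpolation (`numpy.percentile`).
* Coordinates are 1-based inclusive internally; BED output is 0-based
  half-open; the conversion round-trips exactly.
* The truth scorer counts a partial-imprinting truth locus detected at
  the extreme threshold as a correct imprinted call — a parent-of-origin
  locus whose noisy means cross 2.9 is not a false positive.

## Known limitations

* Triple heterozygotes in plain trios cannot be phased and silently
  reduce the number of origin-informative sites.
* The concordance mapper assumes a single local regulatory variant; it
  will map perfect proxies in full LD interchangeably and does not model
  incomplete penetrance of cis effects beyond the 0.9 threshold.
* The IBD concordance analysis requires a three-generation family;
  trio-only panels yield no informative pairs.
* Reported problem sizes (60-locus, 39-individual default panel; 50,000
  calibration heterozygotes) are the package's test-scale defaults;
  genome-scale runs are a matter of input size only, all algorithms
  being linear or locally quadratic in informative SNPs per segment.
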