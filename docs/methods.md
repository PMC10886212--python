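# Methods

This note documents the statistical model behind `selsig`, the parameters
that matter, the numerical conventions, and what the bundled simulator does
and does not emulate.

## Data model

Genotypes are held as a samples × variants matrix of alternate-allele
dosages (0/1/2; −1 = missing) with a variant table (chrom, 1-based pos, id,
ref, alt) and a sample table (id, population). Missing calls are propagated,
never imputed, except where a method requires a complete matrix (PCA,
below). Positions are 1-based inclusive everywhere internally and in TSV
output; BED output is 0-based half-open.

## Quality control

Filters run in a fixed order — call rate, autosome membership, MAF, exact
HWE — so the per-stage removal counts in the QC report are well defined.
The order does not change the retained set (each filter is a property of the
variant alone), only the attribution of a variant that fails several
filters. Defaults: call rate ≥ 0.90, autosomes {"1"…"18"} (pig karyotype;
configurable), MAF ≥ 0.05, HWE p ≥ 10⁻⁶.

The HWE test is the exact conditional test: given the observed allele
counts, the probability of each attainable heterozygote count is
P(h) ∝ n! 2ʰ / (n_AA! n_Aa! n_aa!), and the two-sided p-value sums the
probabilities of all counts no more probable than the observed one.
Computation uses log-gamma with normalization inside the enumeration, exact
to < 10⁻¹² against a rational-arithmetic oracle for allele totals ≤ 60.

MAF and HWE are computed on all samples pooled by default, matching
single-cohort QC tools. Pooling two diverged populations inflates HWE
failures (Wahlund effect); `hwe_per_population=True` tests within each
population instead and removes a variant that fails in any of them. With
the background differentiation this package targets (F ≈ 0.03) the pooled
test loses only a small fraction of variants, which is why pooling remains
the default.

## Population structure

**PCA.** Each variant is standardized by its estimated allele frequency:
mean 2p̂ and sd √(2p̂(1−p̂)) (Patterson/EIGENSTRAT scaling; `unit` and
`none` are available). Missing dosages are replaced by the variant mean
before scaling — the only place the package imputes — because
eigendecomposition needs a complete matrix and mean imputation is neutral
for centered data. Monomorphic variants are dropped with a logged count.
Coordinates are U·S from the SVD of the standardized matrix; variance
explained is the eigenvalue fraction over all components. Component signs
are fixed deterministically (largest-magnitude coordinate positive).

**IBS.** For a sample pair, over variants called in both: similarity =
Σ(2 − |dᵢ − dⱼ|) / (2L); distance = 1 − similarity. Pairwise-complete
variants are used rather than imputation. A pair with no jointly-called
variant is an error, not a silent zero.

**Neighbor joining.** Saitou–Nei agglomeration with the Studier–Keppler
criterion Q(i,j) = (n−2)d(i,j) − r(i) − r(j). Ties in the Q minimum break
to the lowest (row, col) pair; negative branch lengths are clamped to zero
with the deficit moved to the sibling branch; the last three nodes join in
one trifurcation (unrooted convention); children are ordered by first-seen
label so the Newick serialization is reproducible. On additive matrices the
algorithm is exact, which the tests verify against the generating tree and
against scikit-bio's independent implementation.

## LD decay

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples — composite (genotype) LD, the appropriate
statistic when phase is unknown, as on chip data. Pairs are restricted to
the same chromosome within `max_dist` (default 500 kb) and averaged in
contiguous distance bins (default 1 kb); empty bins are reported as empty,
never interpolated. Because LD estimates rise as sample size falls,
per-population comparisons first downsample every population to the size of
the smallest (seeded, without replacement).

r²₀.₃ is the left edge of the first occupied bin from which every later
occupied bin also has mean r² < 0.3. The persistence clause makes the
statistic robust to a single noisy bin dipping below threshold early; a
curve that never settles below threshold reports a "not reached" sentinel.

## Sweep scan

Per SNP with population alt frequencies p̂₁, p̂₂ (requiring ≥ 2 called
alleles in each population):

* H_S = [2p̂₁(1−p̂₁) + 2p̂₂(1−p̂₂)]/2, H_T = 2p̄(1−p̄) with p̄ = (p̂₁+p̂₂)/2;
* per-site diversity π = (n_c/(n_c−1)) · 2p̂(1−p̂), n_c = called alleles.

Windows (default 5 Mb sliding by 100 kb; the bundled scenario uses 1 Mb by
100 kb) aggregate per-SNP terms: F_ST = (ΣH_T − ΣH_S)/ΣH_T as a ratio of
sums — more stable than averaging per-SNP ratios — and θπ per bp = Σπ /
window length. Windows with ΣH_T = 0 have undefined F_ST; windows with
θπ(pop2) = 0 have an undefined ratio; both are excluded from thresholding,
as are windows with fewer than `min_snps` (default 2) SNPs.

Two properties of this F_ST matter for interpretation:

* It is a **ranking statistic**, not an unbiased estimator of the
  population-model F. With two demes the "total" population is the mean of
  the two samples, which halves the apparent among-deme variance, and
  finite samples add ≈ 1/(2n); under Balding–Nichols drift at F = 0.03 with
  n = 50 per deme its expectation is ≈ 0.020. The Weir–Cockerham estimator
  (`fst_estimator="wc"`) corrects both effects and calibrates at ≈ F
  (measured 0.030 on neutral simulations); it is the right choice when the
  absolute F_ST level matters or when comparing to common tooling. The scan
  thresholds on empirical quantiles, so the two estimators select nearly
  the same extreme windows.
* Min–max scaling is strictly monotone, so thresholding scaled or raw
  values selects identical windows — asserted as a test; thresholds are
  computed on raw values and the scaled columns are written for plotting.

Thresholds are nearest-rank empirical quantiles (rank ⌈q·m⌉) applied
inclusively — ties at the threshold are all selected. Selection is the
**intersection** of criteria (`combine="union"` available): sweep in pop1
(the ratio numerator) requires F_ST ≥ q₉₉ and ratio ≤ q₀₁, since a sweep
depletes the numerator's diversity; sweep in pop2 requires F_ST ≥ q₉₉ and
ratio ≥ q₉₉. Overlapping or book-ended selected windows merge into regions
per direction; unique SNPs inside the regions are the candidate SNPs. A
degenerate statistic distribution (all values equal) calls nothing, with a
warning; fewer than 100 usable windows warns about quantile resolution.

## Annotation and enrichment

Classification precedence per SNP: inside a gene → `exonic` if the model
carries exons and the SNP hits one, else `intronic`; otherwise within a
1 kb strand-aware flank of a gene start → `upstream`, of a gene end →
`downstream`, of both (possibly different genes) → `upstream/downstream`;
otherwise `intergenic`, recording the nearest gene on each side up to
`max_flank_search` (default 1 Mb). The categories partition any SNP set.
A UTR category is deliberately omitted: chip-scale gene models rarely carry
UTR structure, and exon overlap covers it.

Candidate genes are the deduplicated union of gene ids attached to
candidate SNPs. Intergenic SNPs contribute their recorded neighbors by
default — on sparse chips most candidate SNPs are intergenic, and without
neighbors the gene lists would be nearly empty; a flag restricts to
genic/flank hits. Enrichment against GMT terms uses the upper-tail
hypergeometric p = Σ_{x≥k} C(K,x)C(N−K,n−x)/C(N,n) with the universe = all
genes in the supplied gene-model file; the significance flag uses raw
p < 0.05 and BH FDR is always reported alongside.

## Synthetic data

The simulator draws, per SNP, an ancestral frequency p ~ U(0.05, 0.95) and
per-population frequencies from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes are Binomial(2, freq) per sample
and missingness is Bernoulli per call. Within a planted sweep interval the
swept population draws with F = `f_sweep` and the resulting frequency is
pushed toward the nearer boundary by exponentiation (`sweep_freq_push`,
default cubic), so diversity depletion and differentiation co-occur — the
signature the intersection rule requires. All draws flow from one seeded
generator; identical parameters give bit-identical output.

Reference scenario (the `SimParams` defaults): 50+50 samples, 18 autosomes
of 40 Mb, ~28 SNPs/Mb (~20,000 SNPs), F = 0.03 background, F = 0.35 swept,
cubic push, 2% missingness, three 2 Mb sweeps per population centered on
chromosomes 1–6. The genome size is chosen so that a 1 Mb/100 kb scan
yields ~7,000 windows: a 1% threshold then admits ~70 windows, the same
order as the ~66 windows fully inside the planted sweeps, which is the
regime a top-fraction selection rule needs to recover all sweeps. Measured
over ten seeds, region-level precision and recall of the scan against the
planted truth both have median 1.0.

What the simulator does **not** emulate: linkage (sites are exchangeable
given their frequencies, so LD-decay structure must come from constructed
haplotype-block fixtures, and the background r² reflects pure sampling
noise ≈ 1/n); ascertainment bias of chip marker selection; genotyping
error; related individuals; and selection modes other than a hard local
sweep. Passing tests therefore demonstrate correctness of the statistics
and of sweep recovery under drift + local diversity depletion, not
performance on real chips with LD-informed marker panels.

Phenotypes are Normal per population (defaults: backfat 14 vs 18 mm,
daily gain 0.159 vs 0.229 kg/d, sd 1 mm / 0.02 kg/d), with ages derived so
that gain ≡ 30 kg / interval exactly. The comparison utility is the
pooled-variance Student's t (Welch by flag), reporting medians alongside,
with the degenerate zero-variance-equal-means case defined as t = 0, p = 1.

## Pipeline determinism

`run_pipeline` executes stages in order into a run directory and writes a
manifest with the configuration, input checksums, and a SHA-256 per
artifact. A single global seed fans out to per-stage seeds by fixed
offsets. All writers are timestamp-free, so a rerun on identical inputs is
byte-identical — asserted by comparing manifests of two runs.

## Problem sizes used in tests

Unit fixtures are ≤ 40 samples × ≤ 60 variants. Simulation-backed checks
use the reference scenario (100 samples × ~20,000 SNPs; ten seeds for the
recovery and calibration medians) or smaller layouts for structure/LD
properties; these sizes give stable medians while keeping the full suite
in tens of seconds.
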