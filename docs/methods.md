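# Methods

`droneselect` re-implements, as a tested library, the bespoke computations
of a drone whole-genome resequencing study design: haploid males are
single recombinant gametes of their queen, so moderate-depth sequencing of
many drones yields phased haplotypes cheaply, and heterozygous genotype
calls — impossible at a unique haploid locus — become a CNV signal rather
than noise.  This note records the models, the defaults and why, what the
synthetic data does and does not emulate, and the numerical choices.

## The FLK model and the hapFLK scan

For populations `j = 1..n` with co-ancestry matrix `F` (shared branch
lengths on a rooted population tree, pure drift, no migration), the vector
of allele frequencies `p` at a neutral site is modelled as

    p ~ N(p0 · 1, p0 (1 − p0) F)

around the ancestral frequency `p0`.  The test statistic is the
Mahalanobis form

    T = (p − p̂0 1)' [p̂0 (1 − p̂0) F]⁻¹ (p − p̂0 1),

with `p̂0` the generalized-least-squares estimate
`(1'F⁻¹p)/(1'F⁻¹1)`, clipped to `[1e-6, 1 − 1e-6]`; a site whose estimate
hits the clip bound is flagged monomorphic and reported with `T = 0`.
Because `p̂0` is estimated, `T` is χ² with `n − 1` degrees of freedom under
the model, which is what the single-SNP p-values use.

Writing `F = Q' D Q` (rows of `Q` = eigenvectors, descending eigenvalues,
sign fixed so each eigenvector's largest-magnitude loading is positive),
`T = Σ u_i²` with `u = D^(−1/2) Q p̃` — each eigenvector of `F` owns an
identifiable share of the statistic, and the loadings `Q_{i,j}` tie
eigenvectors to populations.  The identity `|T − Σu_i²| ≤ 1e-8` is
asserted on every scan.

**Kinship estimation.**  Pairwise Reynolds distances (ratio-of-sums
multilocus estimator) are transformed `t = −ln(1 − D)` — additive under
drift — and a neighbor-joining tree is built (scikit-bio), negative branch
lengths clamped to zero.  Rooting "on the outgroup branch" is implemented
without explicit rerooting: for ingroup populations `a, b` the shared
root-to-leaf length is `(d(o,a) + d(o,b) − d(a,b))/2 − ℓ_o`, with `o` the
outgroup leaf and `ℓ_o` its pendant edge; any point on the outgroup branch
gives the same ingroup paths.  Note the estimated kinship absorbs the
binomial sampling variance of finite samples (Reynolds distances are
computed from sample frequencies), which is what keeps the scan on
genotype data approximately calibrated — the true drift-only `F` would be
anticonservative there.

**Haplotype clusters.**  hapFLK replaces allele frequencies with local
haplotype-cluster frequencies from a fastPHASE-style jump HMM: a hidden
cluster path per haplotype, per-locus cluster allele frequencies θ,
per-locus cluster weights α (also the jump destination law) and
per-interval jump probabilities ρ.  The EM uses scaled forward–backward
(numba-compiled); θ is clipped to `[1e-5, 1 − 1e-5]` and jump-count
updates carry a `1e-9` pseudocount, so the log-likelihood trace is
non-decreasing to within ~1e-6 relative.  "Run for 20 EM iterations" in
the original protocol is read as 20 independently seeded EM *fits* whose
per-locus statistics are averaged (the fit-count semantics of the hapFLK
software); each fit iterates to a relative log-likelihood tolerance of
1e-5 or 200 iterations.  With identical haplotypes the EM optimum is
label-degenerate (several clusters converge to the same θ); this is
expected and harmless since only pooled cluster frequencies enter the
statistic.  At each locus the FLK form is applied to every cluster's
per-population frequency vector (its own `p̂0` per cluster, clipped
clusters contributing zero) and summed over clusters.

**Calibration and regions.**  hapFLK values are not χ² on their nominal
scale; a scaled χ² (scale `a`, df `d`) is fitted to the lower 95% of the
genome-wide distribution — robust to selected outliers — by matching the
first two moments of the *correspondingly truncated* scaled-χ² density
(naive moment matching on a trimmed sample is badly biased; the truncated
moments use `E[Y^k 1{Y≤τ}]` identities of the χ² family).  P-values are
the upper tail of `value/a` at `d` df.  Positions with `p ≤ 1e-4` are
chained while gaps are ≤ 2 kb, extended by 10 kb flanks, clipped at 1, and
overlapping extended regions merged (regions are pairwise disjoint; the
merge prevents double-counting one signal).

**Assignment.**  Per eigenvector `i`, the selection measure of a region is
the sum of `u_i²` over region SNPs exceeding the genome-wide 99th
percentile of `u_i²` (squared contributions, for consistency with
`T = Σu_i²`; the threshold is genome-wide per eigenvector), divided by the
region's SNP count.  The region is assigned to
`argmax_j |Q_{i*,j}|` only when the winning measure is at least twice
every other; ties in the loading are reported, flagged ambiguous, never
silently broken.

## hetSNP clusters as CNV candidates

Filter cascade, applied drone by drone: keep sites on chromosomes 1–16
with per-genotype depth ≥ 9 in *every* individual (the stricter reading of
"DP ≥ 9 across all individuals"); drop hetSNPs whose nearest het neighbour
on the chromosome is > 2 kb away; form maximal runs with inter-het gaps
≤ 2 kb; keep runs with ≥ 3 hetSNPs spanning ≥ 2 kb whose mean depth is
≥ 3× the drone's average.  The drone-average baseline is computed over all
the drone's genotyped sites *before* the depth site-filter — the
genome-wide average is the natural reference for 3× inflation.  Per-drone
clusters overlapping by ≥ 1 bp are unioned into intervals with per-
population carrier counts; intervals carried by more than 15 drones (a
fraction option for other cohort sizes) are flagged as unlikely artefacts.
Population bias is a Pearson chi-squared on the carrier/non-carrier ×
population table without continuity correction, p from the χ² upper tail;
p-values are reported raw (no multiple-testing correction, matching the
convention of reporting per-interval bias).  Annotation flags any 1-bp
overlap with crossover/gene-conversion intervals and lists genes within
2 kb.

## Mitotype reconstruction

Panel references are trimmed to the sequence strictly between the 3' end
of tRNA-Leu (`CTTTTATTAAA`) and the 5' end of COX2 (`ATTTCCACA`); both
motifs must occur exactly once, which also guards double-trimming.  Reads
overlapping the region by ≥ 1 bp are aligned to every reference with a
deterministic local affine aligner (match +1, mismatch −2, gap open −4,
extend −1).  An alignment is "high-quality" when its identity over aligned
bases is ≥ 0.95 with ≥ 30 aligned bases — the package's analogue of the
mapping-quality ≥ 20 gate behind the original PF_HQ metrics; both knobs
are exposed because those definitions are tool-inherited.  Per reference:
`e` = (HQ mismatches + HQ indel events) / HQ aligned bases, `q` = HQ
aligned bases with base quality ≥ 20 / all aligned bases.  References with
`e > 0` and `q > 0.5` are acceptable; lowest `e` at 6-decimal precision
wins, ties go to the longest sequence, residual ties to the smallest
accession with an ambiguity warning.  The `e > 0` rule intentionally
rejects perfect alignments (they would favour very short references); its
corollary is that error-free reads reject their own source — the read
simulator therefore defaults to a nonzero error rate.  The consensus is a
majority-vote pileup against the best reference (ties keep the reference
base; uncovered positions keep the reference base; indels are not applied,
so the output has reference length — mitotype identity is carried by the
selected accession, and indel calling would add failure modes without
changing it).  For network software that masks gappy columns, alignments
are recoded C→G then gap→C (order matters), and segregating sites are
counted after masking columns with > 5% gap/N.

## The synthetic-data generator

The generator reproduces the statistical structure each analysis assumes,
not sequence realism.

* **Drift**: per site, `p0 ~ Uniform(0.05, 0.95)` and
  `p ~ N(p0·1, p0(1−p0)F)` — exactly the FLK covariance, so null
  calibration is a fair test of the statistic.  Draws with any coordinate
  outside (0, 1) are redrawn (up to 10 times, then clipped): raw
  truncation leaves boundary atoms on ~1–2% of sites that measurably
  inflate the FLK tail, defeating the purpose of using the Gaussian
  model.  The redraw conditions the marginal on the interior, which
  slightly shrinks variance for boundary-near `p0` — negligible at the
  default drift levels, visible (≈10%) at `F = 0.1·I`.
* **Default kinship** `diag(0.030, 0.080, 0.020)` with 0.010 shared
  co-ancestry: a moderately drifted honey-production-like population and a
  strongly bottlenecked royal-jelly-like population (closed breeding from
  few queens; such populations separate first in structure analyses)
  against a larger reference population, plus an outgroup lineage at 0.15
  when four populations are simulated.  The asymmetric diagonal matters
  scientifically: it aligns one kinship eigenvector with the bottlenecked
  population and down-weights it in the GLS ancestral-frequency estimate,
  which is what makes spectral assignment decidable — with three
  near-equal drift coefficients the eigenvectors are arbitrary rotations
  and the 2× rule cannot fire.
* **Haplotypes**: within LD blocks of 20 sites, each population draws a
  founder pool of 16 haplotypes (site-wise Bernoulli from its frequency
  vector) and each sample copies one founder per block; block boundaries
  act as recombination points.  Sixteen founders keep the founder-sampling
  variance of cluster frequencies below the drift signal (a much smaller
  pool imposes bottleneck-level homozygosity that swamps the scan).  No
  coalescent realism is attempted — hapFLK needs block LD, not
  genealogies.
* **Depth**: per-drone mean `~ N(12, 1)` times a per-site Gamma(30, 1/30)
  multiplier shared across drones (mappability-driven depth correlation),
  rounded.  The sharing is essential: under independent per-call noise the
  "DP ≥ 9 in every individual" site filter would discard essentially every
  site.  A 12× baseline leaves a usable site set after that filter.
* **Het noise**: 0.5% of haploid calls are flipped to heterozygous
  (matching the order of magnitude of hetSNP calls per genotyped site in
  real drone data).  Noise hets lack depth inflation, so the 3× depth rule
  removes them — which is exactly the discrimination the null CNV control
  verifies.
* **CNV injection**: carriers gain het calls at segment sites with
  probability 0.15 (site spacing 200 bp × 10 kb segment ≈ 50 sites ≈ 7
  expected hets) and 3× depth; a carrier realising fewer than the
  requested minimum het count has its diverged positions redrawn
  (bounded), since the het density is a stated condition of the
  experiment, and the generator asserts it.
* **Mitotypes**: anchor + optional P element + 1–3 tandem Q elements +
  anchor, with injected SNPs; the P/Q element sequences are synthetic
  AT-rich stand-ins of realistic lengths (54 / 196 bp), not database
  material.  Reads are uniform-start substrings with substitution errors
  and Normal Phred qualities.  Decoys are built the way real mitotype
  panels vary — Q copy-number variants, P presence variants, and ≥ 2
  diagnostic substitutions applied to the element *templates* before
  assembly (so they appear in every Q copy).  A single-copy edit inside a
  tandem repeat would be invisible to local alignment (reads simply align
  to the unedited copy), turning the benchmark into a test of alignment
  shadowing rather than mitotype selection.

What passing tests therefore show: the statistics are implemented
correctly and are well calibrated *under their own model assumptions*.
They do not show robustness to mapping artefacts, indel misalignment,
batch effects or reference bias, which real drone data exhibit and which
the generators deliberately do not model.

## Numerical choices and degenerate inputs

* π uses the unbiased per-site factor `n/(n−1)` and divides window sums by
  the window length in bp (the convention of the standard windowed-π
  tools, keeping honeybee π on its familiar 0.002–0.006 scale);
  genome-wide π is the unweighted window mean.  Sites with < 2 calls
  contribute zero with a counted warning.
* Reynolds distances with an identically-fixed denominator return 0 with a
  warning; distances must be < 1 for the log transform.
* The depth curve `GX = a(1 − exp(−DP/b))` is this package's choice of
  regression family (the original study's form is unpublished); the fit
  rejects rank-deficient inputs and inversion rejects targets at or above
  the asymptote.
* In-silico diploids pair drones without replacement within populations
  (seeded); haploid het or missing calls propagate as missing; an odd
  drone is dropped with a warning.  Allele counts are conserved exactly on
  het-free input.
* Missing genotypes on the FLK path are dropped per site (the external
  imputation step of the original protocol is out of scope); haplotypes
  entering the cluster HMM impute het/missing to the site-major allele.
* The acceptance script scales replicate counts (8 sweep, 20+20 CNV, 25
  mitotype replicates) as its own choice of problem size; the test suite
  runs the full 20/20/40-replicate versions.

## Known limitations

Biallelic SNPs only; no BAM/CRAM handling (alignments enter as SAM/FASTQ);
no imputation, no ADMIXTURE-style model-based clustering, no network
construction (recoded alignments are exported for external network
software); diploid hapFLK is not implemented; the mitotype aligner is
exact but quadratic, sized for a ~1 kb region, not genomes.
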