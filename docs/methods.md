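# Methods

## The setting

Two lines founded from one base population (a cross of seven partially
inbred lines, so founder allele frequencies are multiples of 1/7) are
selected in opposite directions on a single trait for ~50 generations and
genotyped on a dense SNP chip at generations 40 and 50 (20+20 and 49+10
birds).  The analytical problem is to locate selected regions, separate
selection from drift at the observed fixations, and bound the number of
loci behind the response.  This package implements that analysis as a
pipeline over explicit data types, with a synthetic-data generator standing
in for non-deposited genotypes.

## Forward simulation (`forward_sim`)

An individual-based, two-locus diploid model of one selected line.

* **Breeding scheme.**  Constant census of 288 = 48 dams × 6 offspring;
  12 sires, 4 dams per sire, dams assigned to sires uniformly at random
  each generation.  The scheme is constant across generations.
* **Selection.**  Viability-style fitnesses 1, 1−hs, 1−s for AA, Aa, aa at
  locus A, with separate s for males and females (selection intensities
  differ by sex); h defaults to 0.5 (additive).  Locus B is neutral and
  linked at recombination fraction r.  Parents are drawn within each sex by
  *fitness-weighted sampling without replacement* (exponential race keys:
  sort Exp(1)/w ascending), which honours both the fitness model and the
  fixed parent counts.  The alternative reading — survive, then choose
  uniformly — changes fixation proportions by a few points; the sampling
  scheme is the package's choice and fixation-time acceptance bands are
  wide enough (±5 points / ±4 generations) to cover the ambiguity.
* **Founders.**  2×288 haplotypes i.i.d. from a four-digit code xyzw
  giving sevenths of AB, Ab, aB, ab; sexes Bernoulli(1/2), redrawn in the
  (negligible) event a generation lacks 12 males or 48 females.
* **Fixation** means every individual homozygous for the same allele —
  stricter than sample-level fixation in real genotype data.
* **Implementation.**  All replicates carry a leading axis and step in
  lockstep through vectorised numpy; 1000 replicates × 40 generations run
  in a few seconds.  One seeded generator drives the whole run, so results
  are exactly reproducible; the consumed stream depends only on the scheme
  shape, which makes runs at different horizons share their prefix.

Checks: neutral allele frequency is a martingale; neutral gene diversity
decays at 1−1/(2Nₑ) with fitted Nₑ inside the 27–45 band implied by the
parent counts; the proportion fixed by a given generation is nondecreasing
in s; with s near 1 the selected allele is the fixed allele in every
replicate.

## Synthetic genotype panels (`synthetic_data`)

The generator emulates the *observable* structure of the chip data, not the
full pedigree process:

* **Map.**  Default 5,000 SNPs at ~1 marker/15 kb over five chromosomes
  (three macro at 3 cM/Mb, two micro at 10 cM/Mb); a full-chip emulation
  (57,636 SNPs) is a parameter away.  Positions are near-regular with
  jitter.
* **Linkage.**  SNPs are grouped into blocks of 30–60 kb (the LD scale in
  such bottlenecked populations) sharing one drift trajectory, plus
  N(0, 0.01) per-SNP jitter at interior frequencies.  This reproduces
  clustered fixation without a recombination engine; it does *not*
  reproduce long-range LD decay, so statistics sensitive to LD beyond the
  block scale are outside what passing tests demonstrate.
* **Drift.**  Block founder frequencies are uniform on {1/7…6/7} (shared
  by both lines); each line then drifts independently by binomial sampling
  of 2Nₑ gametes per generation (Nₑ = 35).  Note idealised binomial drift
  reaches absorption faster than a structured breeding population with the
  same Nₑ: alternative fixation by drift alone runs ~2% here over 40
  generations from intermediate frequencies (the exact transition-matrix
  value), versus sub-percent in census-288 populations.  Tests therefore
  check the generator against its own exact Markov-chain expectation.
* **Sweeps.**  A planted sweep drives non-escaped SNPs within
  `half_width_bp` of its centre to fixation for the reference allele in the
  favoured line and the alternative allele in the other line, ramping
  linearly from an onset generation (default fixation−15, matching the
  9–16-generation fixation times the simulator gives for s in the
  0.2–0.9 range).  Escape probability rises linearly from 0 at the centre
  to `edge_escape_prob` (default 0.5) at the boundary — the soft edge of a
  sweep from standing variation.  No quantitative edge law is claimed; the
  parameter exists to make detection non-trivial.
* **Sampling.**  Panels draw 2n gametes per SNP hypergeometrically from the
  line's 2×288-gamete pool and pair them at random (sampling without
  replacement from the census); sizes default to 20/20 at generation 40 and
  49/10 at generation 50.  Missing calls are off by default
  (`missing_rate` exists); mutation and genotyping error are not modelled.

The ground-truth table (per-SNP block, base frequency, sweep membership,
escape flag, per-line trajectory values at sampled generations) suffices to
score any detector's sensitivity and specificity.

## Divergence scans (`divergence_scan`)

* **Allelic χ².**  1-df Pearson test on the 2×2 allele-count table, *no*
  continuity correction — that choice is what makes the statistic equal the
  total allele count N at complete alternative fixation (80 for 20 vs 20
  birds, 118 for 49 vs 10), the natural ceiling of a scan.  Monomorphic
  tables (zero column margin) are undefined, flagged, and excluded from the
  Bonferroni denominator, which is recomputed per comparison.  Fisher's
  exact test is available for thin tables; missing genotypes drop out of
  counts per SNP.
* **Smoothing.**  Centered 20-marker moving average within chromosome,
  shrinking at the flanks; optionally normalised by the group-size maximum
  χ² so scans at different sample sizes share one axis.
* **Block scan.**  |Δp| between two generations of one line, averaged over
  non-overlapping 5-SNP blocks within chromosomes (trailing partial blocks
  dropped).  Outlier = block mean strictly above the genome-wide 95th
  percentile (linear-interpolation quantile; ties resolved downward, so at
  most 5% of blocks are outliers).  Windows of 20 blocks slide by one
  block; under independent blocks the window outlier count is
  ~Poisson(1), and a window is significant when its count reaches
  k* = min{k : P(Poisson(1) ≥ k) ≤ 10⁻⁵} = 9.  Blocks are *not*
  independent at the LD scale, so the threshold is conservative in intent
  rather than exact.
* **Heterozygosity.**  H_o per SNP = fraction of heterozygous calls;
  line-level decline between generations is compared across lines by a
  two-sample two-sided t-test on per-locus decreases (degenerate variance
  → t reported, p undefined).

## Sweep clusters (`sweep_clusters`)

Maximal runs of DIFF-fixed SNPs with ≤1 Mb between successive members;
`min_snps` of 2 (liberal) or 5 (conservative).  Cluster length is
last−first bp (1-based inclusive coordinates), converted to cM by the
chromosome's single cM/Mb ratio — no local recombination map; chromosomes
without a ratio (Z) get a blank map length.  The "genome covered"
denominator is the marker-spanned genome: Σ per chromosome (max − min
marker bp).  The Z chromosome is treated as diploid like the autosomes.
QTL-interval annotation accepts BED (0-based half-open, converted
internally); overlap = any shared bp.

Persistence probability: with per-meiosis escape probability
r·(1−p²−q²) — a crossover lands in the region *and* joins two different
haplotypes — the chance a region survives 2Ng meioses unrecombined is
((1−r)+r(p²+q²))^(2Ng).  N defaults to 36.21, the through-generation-50
harmonic-mean effective size, which reproduces all six reference values of
the 5 cM example to printed precision; it is configurable because the
choice of epoch is genuinely open.

## Quantitative genetics (`quantgen`)

* i(p) = φ(z)/p with z the upper-p normal quantile, computed analytically
  rather than from printed tables (differences < 0.01).
* s = i·2a/σ per sex, capped at 1 with a warning.
* Nₑ = 4NₘNf/(Nₘ+Nf); harmonic mean across epochs takes
  `total_generations` as an explicit numerator because published epoch
  tables do not always sum their printed segment lengths.
* Otto–Jones: T ≈ (a_min·n_d − M)/(n_d−1), n = D/(M−T); raw value kept,
  report rounds half away from zero (120.8 → 121).  M ≤ T raises — the
  estimator is undefined when the detected effects leave no room for
  undetected loci.
* Drift attribution: p_diff = 2·P_fix(A)·P_fix(a); fraction attributed to
  selection = max(0, (observed − n·p_diff)/observed).  Under a uniform
  founder spectrum the six starting configurations are equally likely, so
  expectations are unweighted means over the three unordered pairs.

## Pipeline (`pipeline` / `cli`)

One YAML config drives synth → scan → blockscan → clusters → quantgen and
batched simulations; every artifact is TSV/JSON with a sha256-checksummed
manifest, and identical config+seed gives identical checksums.  A stage
failure aborts downstream stages.  Defaults throughout match the
experiment's stated parameters (12/48/6 scheme, h = 0.5, 1 Mb gap, 5-SNP
blocks, 20-block windows).

## Problem sizes

Tests run the generator at 800–6,000 SNPs and the simulator at 40–500
replicates; the acceptance script uses the full 1,000 replicates for the
three simulation quantities.  These sizes give Monte-Carlo standard errors
of 1–2 percentage points on fixation proportions, small against the ±5
point acceptance bands.

## Known limitations

* Two loci only; no mutation; no explicit truncation selection on a
  quantitative phenotype (s summarises it).
* The generator's block-drift emulation has no within-block recombination
  and an idealised absorption rate (above).
* Sliding-window flank handling and the sweep edge law are package choices
  where no standard exists.
* The Fst formulation of between-line differentiation is not implemented
  separately: the allelic χ² carries the same information at a 2×2 table.
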