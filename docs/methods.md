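# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical choices, what the synthetic generator does and does
not emulate, and the known limitations. It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mutual-information network inference

**Estimator.** Plug-in MI in bits on an equal-frequency discretization of
ordinal (stable) ranks: bin(i) = ⌊rank·B/n⌋. Rank binning makes the
estimate exactly invariant under strictly monotone transforms of either
profile, so the inference is indifferent to the normalization scale of the
input matrix. Default bin count B = max(2, ⌊√n/2⌋) (7 bins at n = 200) —
coarse enough that each cell of the B×B joint table holds several samples
at cohort sizes where MI inference is sensible (n ≳ 80), fine enough to
register non-monotone dependence. A constant profile carries no
information and is assigned MI 0 with a warning rather than an error,
since expression matrices routinely contain flat probes.

**Significance.** A pooled permutation null: `n_perm` (default 1000) MI
values computed between TFs and sample-permuted target profiles, pooled
across pairs. A per-pair null at this resolution would cost n_pairs times
more; pooling is valid here because rank binning makes the null MI
distribution identical for every pair (it depends only on n and B, not on
the marginals). Empirical p = (1 + #{null ≥ observed})/(1 + n_perm), BH
across all TF–target pairs, edge kept at adjusted p < α (default 0.05).
The permutation count bounds the smallest attainable p at 1/(n_perm+1);
the constructor refuses configurations that cannot resolve α.

**DPI pruning.** For every fully connected triple of significant edges,
the edge (a,c) is removed when MI(a,c) < min(MI(a,b), MI(b,c))·(1−ε),
strictly — ties keep the edge (conservative). All removal decisions are
evaluated on the pre-pruning network so the result is order-independent.
Default ε = 0 (strictest pruning); ε = 1 disables pruning. TF–TF edges are
allowed, so a TF can sit inside another TF's regulon and mediate a chain.

**Mode of action.** Each surviving edge is annotated with the sign of the
Spearman correlation between TF and target. For genuinely non-monotone
(e.g. quadratic) dependence the sign is close to arbitrary; MI still
detects the edge, which is the point of using MI at all.

## Differential-expression signature

Welch two-sample t per gene on log-scale values, log₂FC = mean(B) −
mean(A), BH across genes; members = genes with adjusted p < α (default
0.05) and |log₂FC| ≥ 1. This is a deliberately plain DE statistic: no
variance shrinkage, no covariates. A signature computed by any external
tool can be imported as GMT and used unchanged downstream. Degenerate
zero-variance genes: unequal means give p = 0 (decisive), equal means
p = 1; both logged.

## Master regulator analysis

One-sided hypergeometric tail P(X ≥ k) for the overlap k between a regulon
and the signature inside the universe, BH across regulons. The universe is
the set of genes present in that network's expression matrix — enrichment
is conditional on what was measurable — and members outside it are dropped
with a warning. Consensus MRs must be significant in **both** disease
networks (strict intersection). The specificity filter then removes TFs
that are (i) MRs of the *same* signature in a control-tissue network, or
(ii) MRs of a proliferation signature in either disease network; every
exclusion is logged with its reason. The filter is monotone: enlarging
either exclusion set can only shrink the final set. Regulon agreement
across networks is reported as overlap counts, percent of the smaller
regulon, and Jaccard similarity; Jaccard(∅,∅) is defined as 0.

## Motif scanning and enrichment

**PWM.** frequency(b,j) = (count + pc·bg_b)/(total_j + pc) with
pseudocount pc = 0.1; log-odds in bits against a 0-order background
estimated from the supplied FASTA by default (uniform optional).

**Threshold.** The exact null score distribution is computed by dynamic
programming over positions on a score grid of 0.001 bits; the threshold is
the smallest grid score whose tail probability is ≤ the requested scan p
(default 1e-4). Because scanning uses exact (un-rounded) window sums, the
returned threshold is lowered by half a grain per position so grid
rounding can never exclude a word the DP counted. For motifs shorter than
7 bp under a uniform background the minimal attainable tail 1/4^L exceeds
1e-4; the threshold then falls back to the maximum score (only the
consensus word and its reverse complement match), with a warning.

**Scanning.** Every window is scored on the forward strand and against the
reverse-complement PWM at the same forward coordinates; windows containing
N are skipped and counted. A gene "carries" the motif if any window on
either strand reaches the threshold, which makes the carrier set invariant
under reverse-complementing the input.

**Enrichment.** The observed carrier count inside the regulon is compared
with the carrier counts of regulon-sized gene sets resampled uniformly
without replacement from the universe (default 100,000 draws). The carrier
count of such a draw is exactly hypergeometric, so the null sample is
drawn directly from that distribution — distributionally identical to
materializing each subset, at O(n_samples) cost. The reported z is the
plain standardized count; the one-tailed p applies a half-count continuity
correction, without which a normal tail cannot track the discrete
P(X ≥ k) (the gap is half the probability mass at k, up to ~0.07
mid-distribution). The exact hypergeometric tail is always reported
alongside as the infinite-resample limit; for strongly skewed nulls (rare
carriers, small regulons) the normal approximation can still deviate by
more than 0.01 and the exact tail is the number to trust. Degenerate
universes (all or no genes carry the motif) yield an explicit degenerate
result rather than a p-value.

## Survival engine

Kaplan–Meier product-limit estimator with Greenwood variance; records
censored at an event time remain at risk for the events at that time. The
log-rank test uses the hypergeometric variance at each distinct event time
and is implemented vectorized over many group assignments at once, which
is what makes the permutation machinery below affordable. Cox proportional
hazards (single covariate) maximizes the Efron partial likelihood by
damped Newton iteration (step halving until the likelihood does not
decrease, convergence at |Δβ| < 1e-9, cap 50 iterations); Breslow ties are
available via a flag. Monotone likelihoods (perfect separation) are
reported with a `diverged` flag instead of a spurious finite estimate.
With untied event times and a binary covariate, the score test at β = 0
coincides with the log-rank statistic; the test suite checks this identity
to 1e-6 and cross-checks KM, log-rank, and Cox against lifelines.

**Optimal cutoff scan.** The covariate is dichotomized at every integer
percentile from 25 to 75 (nearest-rank), the log-rank p computed for each,
and the minimum selected — the conventional "optimal cutoff" result, which
is optimistically biased because ~51 correlated tests were scanned. The
scan therefore also reports a permutation-adjusted p: the covariate is
shuffled against the fixed survival data (default 1000 shuffles), each
shuffle's own minimum scanned p is found, and the adjusted p is the
add-one-smoothed fraction of shuffles at least as extreme, floored at the
nominal selected p (a lower bound by construction of the selection). Both
numbers are reported side by side: the nominal one for comparability with
the conventional procedure, the adjusted one for calibrated inference.

**Group comparisons.** Relative expression = per-sample value divided by
the gene's mean over all samples (output mean exactly 1). Pairwise Welch
t-tests between labeled groups use Bonferroni correction for up to 4
groups and BH beyond that, with raw and corrected p both reported.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not microarray physics. Regulator profiles are i.i.d. standard normal per
sample; each target is sign·slope·x (or sign·slope·x² in quadratic mode)
plus N(0, noise_sd²) with one regulator per target (tree-structured truth,
so DPI behavior is unambiguous); background genes are pure noise. Chain
mode (A→B→C) exists specifically to exercise DPI. Target-to-TF assignment
is randomized so that independently planted structures (disease vs control
tissue) never share regulon composition by construction. Two-condition
cohorts shift the driver TF's mean by an effect size in sd units, which
propagates to its regulon through the generative slopes. Flank sequences
are i.i.d. uniform ACGT (configurable GC) of length 2·flank_len with one
motif-consensus occurrence planted at a uniform position/strand at rate
`hit_rate_in` inside the regulon and `hit_rate_out` outside. Survival
cohorts are exponential proportional-hazards with standard-normal
covariate and independent exponential censoring.

Defaults are the benchmark study condition used throughout the tests:
20 TFs × 30 targets, 200 background genes, n = 200 samples, slope 1,
noise sd 0.25 — a strong but realistic regulon signal for MI inference at
cohort sizes where the method is recommended. The bundled demo study is a
smaller instance (8 TFs × 20 targets, n = 120, flank_len 300) sized so the
full pipeline runs in seconds; the contrast uses 30 samples per group with
a 2 sd driver shift, the survival cohort n = 200 with true log hazard
ratio ln 2.

What passing tests on this generator show: the estimators are exact
against oracles, the pipeline recovers planted structure under its own
model assumptions, and every test is calibrated under its null. What they
do not show: robustness to batch effects, heavy-tailed noise,
probe-to-gene mapping artifacts, copy-number structure, shared regulators
per target, or confounded survival covariates — none of which the
generator emulates.

## Determinism

Every stochastic step takes an explicit seed (`numpy.random.default_rng`;
no global state). The pipeline derives one seed per stage by hashing the
stage name with the global seed, so stages re-run in isolation reproduce
their part of the bundle. The results bundle carries a SHA-256 checksum
over its canonical JSON (wall-clock metadata excluded); identical
config + seed yields an identical checksum.

## Known limitations

- The pooled permutation null assumes exchangeability across pairs; it is
  exact here because rank binning strips the marginals, but it would be
  approximate for estimators whose null depends on the marginal law.
- The MI estimator's plug-in bias is not corrected; edge *ranking* and
  permutation calibration are unaffected, but MI values should not be read
  as absolute dependence strengths.
- Single-covariate Cox only; no multivariate adjustment, time-varying
  covariates, or competing risks.
- The motif model is 0-order background with a single PWM; no higher-order
  background, motif discovery, or conservation weighting.
- GSEA-style weighted enrichment is intentionally out of scope; MRA here
  is the exact hypergeometric overlap test.
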