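# Methods

This note documents the models and procedures implemented in `dgetag`, their
assumptions, the parameters that matter, and the design choices made where
the methodology was genuinely open.

## The assay model

Tag-based DGE profiling counts 21-nt tags anchored at NlaIII (CATG) sites of
transcripts. The package models the assay as follows:

- **Reference tags.** Every CATG occurrence with at least 17 nt downstream
  yields one reference tag per strand. Sites with fewer than 17 downstream
  nucleotides yield nothing: the chemistry cannot produce a full 21-mer.
  `site_rank` counts sites from the 3′ end of the strand-oriented sequence;
  rank 1 is the tag complete digestion produces, ranks 2+ arise from partial
  digestion or alternative 3′ ends. Ambiguity is defined **across genes**
  (a sequence carried by two genes is ambiguous; two sites of one gene
  sharing a sequence are not), strand-collapsed. Isoforms of one gene are
  merged by sequence, keeping the smallest rank.
- **Cleaning.** Filter order is adaptor → N-containing → copy-number-1, so
  singleton status is judged on assay-valid tags. "Low quality" is modeled
  as ≥ 1 ambiguous base (N); adaptor contaminants as a fixed 9-nt prefix.
  These are stated modeling choices — assays report these filter classes
  without defining them operationally.
- **Mapping.** At most one mismatch (tolerating polymorphisms and residual
  sequencing error), resolved by tier: exact sense > exact antisense >
  1-mismatch sense > 1-mismatch antisense. Within a tier, > 1 candidate gene
  ⇒ ambiguous; within a gene the most-3′ site wins. The priorities make
  assignment deterministic; only unambiguous sense tags quantify genes
  (ambiguous and antisense tags are tallied in summaries). A `rank1_only`
  switch restricts counting to 3′-most sites; the default sums all
  unambiguously assigned sense tags.
- **Saturation.** Subsampling is nested (grid points are prefixes of one
  shuffled tag stream), which guarantees monotone discovery curves per seed.

## Differential expression

With one pooled library per condition and time point there are no replicates,
so dispersion cannot be estimated; the appropriate statistic is the exact
conditional test for two counts. Conditional on x in a library of N₁ tags,
the null law of y is negative binomial with size x+1 and success probability
N₁/(N₁+N₂); both tails are regularized incomplete beta integrals
(`scipy.special.betainc`), so no explicit summation is needed and far tails
retain full relative precision. Two-sided p doubles the smaller tail, capped
at 1.

**Symmetrization.** The conditional law's tails are not exactly invariant
under swapping the libraries (relative differences can reach ~2× deep in the
tails). So that results never depend on library order, the reported p is the
**maximum** of the two conditionings (y|x and x|y). The maximum of two valid
p-values is a valid (conservative) p-value, and the convention is exactly
symmetric. The test suite validates both conditionings against brute-force
log-space tail summation to < 10⁻⁹ relative error.

Fold change is log₂((y/N₂)/(x/N₁)); when either count is zero a pseudo-count
(default 1) is added to **both** counts so on/off genes report finite values.
FDR is Benjamini–Hochberg step-up (`statsmodels`). Calling requires all three
of p, q, and |lfc| to pass; both threshold presets used in this kind of study
are shipped (`methods`: 0.005/0.01/0.5; `results`: 0.009/0.02/0.5) and
neither is asserted as canonical.

## Temporal clustering (STC)

Model profiles are integer change vectors in [−c, c]^(T−1); positive entries
mean up-regulation between consecutive time points (negatives down — the
only sensible reading). Selection is greedy max–min dispersion over the full
candidate space under distance 1 − Pearson correlation of the implied value
series, seeded at the flat profile; correlations involving a zero-variance
series count as 0, and ties (within 10⁻⁹, which makes tie-breaking robust to
float rounding) go to the lexicographically smallest change vector. The
selection is a pure function of (T, c, m); defaults c = 2, m = 80.

Gene series are anchored log-ratios v_t = log₂((TPM_t+1)/(TPM₁+1)) with a
minimum-expression filter (default max TPM ≥ 5 — the filtering criterion is
a package choice, exposed in config). Assignment is argmax Pearson
correlation; zero-variance (anchored all-zero) series are by construction the
flat pattern and go to the flat profile. Significance: for each permutation
of the time-point order the raw columns are permuted, re-anchored and
re-assigned; the expected count per profile is the permutation mean, the
observed count is tested against Binomial(G, expected/G) one-sided, BH
corrected across profiles (the "standard hypothesis testing" step made
concrete). When T! ≤ n_perm all orderings are enumerated exactly.
Significant profiles group by single linkage on profile–profile correlation
≥ 0.7 (transitive closure).

## Enrichment

One-sided hypergeometric over-representation (under-representation behind a
flag), χ² with continuity correction reported alongside, BH FDR, significance
flagged at p < 0.05. The enrichment ratio is the standard fold enrichment
Re = (m/n)/(M/N). The universe is the set of genes detectable in the compared
libraries (≥ 1 mapped tag), not the whole annotation, to avoid detectability
bias. Gene sets are read from GMT files; no GO-graph propagation is applied.

## Library similarity

Pearson correlation over log₂(TPM+1) (log-transform is the standard
preprocessing for expression clustering; exposed as a flag), average-linkage
agglomeration on 1 − r (single/complete also available), Newick export with
branch lengths equal to merge-height differences. Zero-variance libraries
yield undefined correlations and are dropped from clustering with a warning.

## Signal-flow (CTRNN) network inference

The abstract dynamic model is a leaky additive CTRNN,
dx/dt = −a⊙x + W·σ(x) + b with logistic σ, integrated by forward Euler with
step Δt ∈ (0, 1] (default 0.5). No published equations or hyperparameters
exist for this stage, so the fitting procedure is entirely this package's
design: W is masked to the prior (pathway) edge set and (W, a, b) minimize
the teacher-forced one-step squared error plus λ‖W‖₁, by proximal gradient
descent (soft-thresholding for the L1 term) with per-epoch backtracking, so
the recorded objective is nonincreasing; initialization is small random from
the seed, making fits deterministic. Defaults: λ = 0.001, learning rate 0.2,
5000 epochs, reporting threshold |W| ≥ 0.2. Edges report activation (W > 0)
or inhibition (W < 0); "indirect" labels come from the prior's flag, never
from inferred transitivity. One model is fitted per condition across its full
time series.

**Identifiability.** With ~10 time points, an edge is recoverable only if the
regulator's σ(x) varies over the trajectory; when a regulator sits in a flat
stretch of the logistic, its influence is absorbed by the target's decay and
bias terms and the L1 penalty zeroes the weight. The planted-network
benchmark therefore uses trajectories whose initial displacement sweeps σ
through its nonlinear range (weights ±3, x₀ ∈ [−2, 2], observation noise
SD 0.05) — informative but noisy, what the method can honestly be expected
to handle at this series length.

## Synthetic data generator

The generator emulates the structure of a two-condition, ten-stage pooled-RNA
tag study; because pooling yields one composite library per time point, it
models one expression vector per library with no replicate structure.
Defaults and what they emulate:

- `library_depth` 2×10⁵ — a ~20× scale-down of real multi-million-tag
  libraries; full scale is a config change.
- `lognormal_sigma` 2.0 — heavy-tailed abundance, so high-copy tags (> 100
  copies) carry the majority of total clean tags while remaining a small
  minority of distinct tags, the qualitative signature of such libraries.
- `base_error_rate` 10⁻³ per base — produces near-miss tags (≈ 2.1% of tags
  carry ≥ 1 substitution), mostly removed by the singleton filter or absorbed
  by 1-mismatch mapping.
- `adaptor_rate` 0.02, `lowq_rate` 0.03, `antisense_rate` 0.10 — contaminant
  and antisense fractions of the same order as real libraries report.
- `site_rank_probs` (0.85, 0.12, 0.03) — most tags from the 3′-most site,
  a minority from ranks 2–3 (incomplete digestion / alternative 3′ ends).
- Planted effects: half the DE genes get a ±`effect_log2fc` condition effect
  at prenatal stages (t < `divergence_boundary`), half follow temporal
  profiles whose **amplitude** (max |log₂ deviation from t₁|) equals
  `effect_log2fc` — bounding amplitude rather than per-step change keeps
  planted genes from dominating the library composition.
- Planted genes are drawn between the `de_baseline_quantile` (default 0.5)
  and 0.95 abundance quantiles: below that an exact count test has no power
  at desk-scale depth (a gene expected at 2 tags cannot show significance),
  and planting multiplicative effects on the extreme tail shifts the whole
  composition, inducing spurious global fold changes. Detectability and
  compositional balance of planted genes are part of the study conditions.

What the generator does **not** model: read-level quality scores, PCR
duplicates, GC bias, isoform structure, replicate variability. Passing tests
therefore demonstrate correctness of the pipeline's statistics and machinery
under multinomial sampling with the stated error processes — not robustness
to every artifact of real sequencing data.

## Numerical and scale choices

Benchmark problem sizes were chosen for desk-scale runs on one CPU: null
calibration uses 50 simulations of 1000 genes at depth 2×10⁵; DE recovery 20
seeds with 50 planted genes; STC detection 20 seeds at T = 4 (where the 24
orderings can be enumerated exactly); network recovery 20 seeds of 5-gene
networks over 10 time points; the demo pipeline is 1000 genes × 20 libraries
at depth 2×10⁵ and completes in well under a minute. The whole pipeline is
deterministic given the config seed — all generators derive from
`numpy.random.default_rng` seeded per stage and library — and the output
manifest records SHA-256 checksums so reproducibility is byte-verifiable.

## Known limitations

- No replicate-aware dispersion modeling: the exact test treats each library
  as one multinomial draw, as the pooled design dictates; biological
  variability between pools is not captured.
- Ambiguous tags are discarded, not probabilistically rescued.
- The CTRNN stage reports regularized point estimates, not confidence
  intervals; with short series, absent edges cannot be distinguished from
  unexcited ones.
- The copy-number and mapping-fraction figures printed by the demo depend on
  the synthetic configuration and match real-library values only in
  direction, not magnitude.
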