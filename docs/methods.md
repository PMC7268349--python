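# Methods

## The inference model

Sorting a cell population by reporter expression and sequencing each bin
turns a continuous phenotype into per-guide count vectors. Because the
sorter records what fraction of cells fell in each gate, the expression axis
can be quantile-normalized to a standard normal reference: a gate capturing
quantiles (q0, q1) becomes the Z interval (Φ⁻¹(q0), Φ⁻¹(q1)). Bins need not
tile the whole axis — an unsorted middle is allowed, and no renormalization
is applied to the gate fractions.

Cells carrying guide g are modeled as Normal(μ_g, 1) on this axis. Using a
shared unit σ is justified when most guides are inert, so the overall
distribution's spread is the no-effect spread; per-guide variance is
deliberately not estimated. The occupancy of bin b is
S(b, μ) = Φ(Z_b1 − μ) − Φ(Z_b0 − μ), and the expected share of bin b's reads
belonging to g is the guide's unsorted-library fraction scaled by
S(b, μ)/S(b, 0). Reads are negative-binomial: the log-mass of count r_gb
given bin total R_b is log NB(r_gb; size = R_b, prob = 1 − P_b(g|μ)). The
per-guide likelihood is the sum over bins, maximized over μ.

A pseudocount of `pseudocount_rate` reads per million of bin coverage
(default 10, i.e. 10·R_b/10⁶ reads) is added to each sorted-bin count before
fitting. It acts as a prior favoring μ = 0 for guides with too few reads to
be quantified. The pseudocount is applied to sorted bins only: the unsorted
column defines the library composition r_∅g/R_∅ and is left untouched, since
the prior's purpose is to stabilize the bin profile, not the library share.
Guides absent from the unsorted library cannot be scaled at all; they are
retained in the output with μ̂ = 0, log-likelihood ratio 0, and an
`unquantifiable` flag so row counts are stable across experiments.

Because inert-but-targeting guides are part of the distribution being
sorted, real effects shift the quantile reference itself; the raw μ̂ of a
truly null guide is therefore biased by the screen's overall effect
composition. Subtracting the mean μ̂ of the negative controls removes this
bias exactly, giving guide Z-scores whose control mean is identically zero.
The median is offered as a robust alternative centering, but the mean is the
default. Natural logarithms are used throughout; only likelihood ratios and
argmaxima matter downstream.

When wild-type and null-mutant log-FACS expression levels (EL_WT, EL_NULL)
are available, `percent_of_normal_expression` maps Z-scores back to a
percentage scale via x = σZ + μ_log and
%EL(x) = 100·(10^x − 10^EL_NULL)/(10^EL_WT − 10^EL_NULL).

### Optimizer

The likelihood is smooth and in practice unimodal in μ. The maximizer is
found by a bracketing scan — 201 points across the search interval
(default ±5 SD, far beyond any realistic FACS shift, and always including
μ = 0) — followed by repeated 10× grid refinement of the bracket until the
grid spacing falls below the tolerance (default 1e-4 SD). This is
implemented vectorized across all guides of an experiment, which makes the
simulation studies roughly two orders of magnitude faster than per-guide
scalar optimization while agreeing with a brute-force likelihood scan to
within one grid step (asserted in the tests). The combinatorial log-gamma
terms of the NB mass are independent of μ and are omitted during
optimization; they cancel in the reported log-likelihood ratio.

## Element-level statistics

Three statistics are computed per element and experiment from its member
guide Z-scores: the effect size (mean Z, an estimate of the element's
expression shift in SDs), the Stouffer Z (ΣZ/√n), and a significance Z. Raw
Stouffer Z-scores are not calibrated — guide-level noise varies between
experiments and with the number of guides — so each is divided by the
standard deviation of a matched null: every negative-control Z is replicated
`resample_factor` times (default 10), and `n_draws` (default 10,000) sets of
k = n_guides values are drawn without replacement from this pool and
Stouffer-combined. Draws use rejection sampling of index tuples when
k² ≤ pool size (exactly uniform, no Python-level loop) and a random-key
argpartition otherwise; the control pool is sorted first so results are
invariant to guide input order. A zero-variance null (identical controls, or
a draw that exhausts the pool) raises an error rather than producing
infinite significance.

The scaled statistic is standard normal under no effect; p_up and p_down are
its upper/lower normal tail probabilities. The two-tailed value is reported
as p_either = min(1, 2·min(p_up, p_down)) — doubling keeps it a valid
p-value, whereas the bare minimum of the two tails is anti-conservative by a
factor of two; the raw minimum is still emitted as a `p_min` diagnostic
column. Benjamini-Hochberg adjustment (via statsmodels) is applied per
experiment, separately for each tail family.

Elements are defined either by an annotation column (one result per label
with ≥ `min_guides` members, default 5; smaller groups are dropped with a
warning) or de novo by a sliding window: for each chromosome, all windows of
width `window_bp` (default 500; tiling screens with denser coverage may
prefer 200) anchored at guide positions are enumerated, guide sets are
deduplicated, and each distinct set with enough members is scored. Anchoring
at guide positions enumerates every distinct guide set a continuously
sliding window can produce; windows are half-open ([anchor, anchor +
window_bp)), and reported coordinates span the min-to-max member guide
position because the window grid itself is arbitrary. Replicate combination
(`combine_replicates`) calls an element only when it meets the FDR threshold
in every replicate with a consistent effect direction.

## The simulator

The generator mirrors the screen's physical stages with one seeded RNG in a
fixed draw order (library → cells/expression → bin reads → unsorted reads),
so a config and seed fully determine the output:

- guide abundance A_g ~ Poisson(`library_mean`, default 1000) — library
  construction noise;
- cells per guide S_g ~ Poisson(A_g);
- per-cell expression Normal(μ_g, 1) in mean-altering mode, or a mixture in
  proportion-altering mode: with probability r_g the cell responds and is
  shifted by `responder_shift` (default 1 SD). Cells are assigned to bins by
  their Z bounds (left-closed intervals);
- reads per guide per bin r_bg ~ NB(size = d·Σ_i S_bi, prob = 1 − S_bg/Σ_i
  S_bi) with d = `read_depth_factor` (default 10 reads per sorted cell),
  drawn independently per guide; the unsorted library is sampled by the same
  rule from the abundances A_g.

The default configuration is the benchmark design: 200 elements × 5 guides
(all guides of an element share its effect) plus 1000 negative controls, six
10% quantile bins on the distribution extremes (0–30% and 70–100%, three
contiguous bins per tail), and effects 0.01–1.00 in steps of 0.01 for the
100 effective elements (responder fractions 1–100% in proportion mode, whose
average effect is r_g·1 SD). For smaller configs the default keeps half the
elements effective with effects evenly spaced up to 1. The simulator
reproduces count tables, not artifacts it does not model: no guide fitness
effects on library composition, no PCR jackpotting beyond NB dispersion, no
off-target activity, and no sorter impurity. Passing recovery tests
therefore demonstrates the estimator is correct under its own generative
assumptions and well-calibrated against its resampled null — not that real
screens are free of those artifacts.

## Bin-design study

`bin_design` evaluates symmetric, tail-contiguous gate layouts (outermost
pair A/F, then B/E, then C/D; 2–6 bins) by simulating screens dominated by
small effects — by default 0.01–0.10 SD, the regime where layouts actually
separate — running the full inference, and recording the Pearson r between
true and inferred element effects (effective elements only) and the number
of effective elements called at 1% two-tailed BH FDR. Replicate seeds are
`base_seed + replicate_index`; means and SEMs over replicates are reported,
and ranking breaks ties by true positives, then label. The full-scale study
uses 1000 effective + 1000 ineffective elements; the test suite and examples
run a 200 + 200 version with 10 replicates, which preserves every ordinal
conclusion (quartile bins best among 2-bin layouts; more bins always better;
poor performance below ~20% total coverage; the 5/10/20% tail-graded scheme
best overall) at about a minute of compute. Only grid evaluation over named
layouts is performed — no continuous optimization over widths, and no
modeling of sorter-specific gate constraints.

## Numerical choices and edge cases

- Expected read fractions are clipped to [1e-300, 1 − 1e-12] before taking
  logs, so extreme shifts give finite penalties instead of NaNs; degenerate
  NB probabilities in {0, 1} return −∞ from `nb_log_pmf` rather than raising.
- Bin geometry is validated on construction: quantiles in [0, 1],
  non-overlapping bins, total coverage ≤ 1, and Z/quantile consistency to
  1e-9 (1e-6 when both are user-supplied in a bins file, matching the
  precision of typed-in gate fractions).
- Empty bins (zero total reads or zero sorted cells) warn and contribute
  zeros rather than failing the run.
- The log-likelihood ratio is floored at 0: μ = 0 is always in the search
  set, so a negative ratio can only arise from floating-point noise.
- Output tables are sorted deterministically and carry their parameters in
  '#' header comments; identical inputs and seeds produce byte-identical
  files.

## Scale of shipped analyses

The test suite and the acceptance script run the benchmark screens at their
full published design (2000 guides, ~2M sorted cells per screen, 5 seeds per
mode) and the design study at the reduced 200 + 200-element scale with 10
replicates; both finish in a few minutes on a single core thanks to the
vectorized fitter.

## Known limitations

- Proportion-altering (bimodal) effects are summarized by their average
  shift; the mixture itself is not fit, so a 50%-responder element and a
  half-strength uniform shift are indistinguishable by design.
- The null model conditions on the observed control Z-scores; with very few
  negative controls the resampled SD is itself noisy, and at least a few
  dozen controls per experiment are advisable.
- Significance assumes guides within an element are independent; shared
  off-target or positional artifacts violate this and are only partially
  absorbed by the control null.
- FCS flow-cytometry files are not parsed; gate fractions are taken as
  user-supplied quantiles recorded at the sorter.
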