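# Methods

## Data model

A `CtMatrix` holds one quantification-cycle value per (gene, sample),
sample annotations (donor, condition) and a per-gene amplification
efficiency E with 1 < E ≤ 2. Ct values must lie in (0, 45] (45 cycles is
a common instrument maximum; configurable). E defaults to exactly 2
(perfect doubling), matching the usual practice of analysing raw SYBR
Ct values directly; per-gene overrides propagate through every
computation that converts cycles to quantities.

Missing values: strict mode (default) rejects the dataset, naming the
offending cell. Permissive mode drops the affected sample listwise for
all genes, because all four stability algorithms are defined on complete
grids; imputation is deliberately out of scope. The model stores one
value per (gene, sample) — technical-replicate collapsing, if any, is
the caller's responsibility.

Relative quantities are q_gs = E_g^(minCt_g − Ct_gs), referenced to each
gene's own minimum over the current samples, so q ∈ (0, 1] with a
per-gene maximum of exactly 1. The reference point is arbitrary for all
downstream statistics (they are invariant to per-gene constants); the
minimum is used because it keeps quantities in a fixed interval.

## Stability algorithms

All four return per-gene values where lower = more stable, all SDs use
the n−1 denominator, and all logs are base 2.

**Pairwise-ratio M (geNorm).** M_g = (1/(G−1)) Σ_{h≠g}
SD_s[log2(q_gs/q_hs)]. The stepwise ranking removes the highest-M gene
and recomputes until two remain; those two are reported as a tied best
pair at rank 1 (the pairwise criterion cannot separate them), the next
gene takes rank 3, and each gene's reported value is its M at the round
of its exclusion (the applet's ranking semantics; the all-genes-in M
vector is kept in the extras for inspection). Ties at the worst M are
broken by removing the lexicographically later symbol — a determinism
choice; exact ties essentially occur only on constructed data. The
conventional M < 1.5 stability flag is attached.

**Model-based stability (NormFinder).** On y = log2 q, the additive
model y_gs = α_g + β_s + ε_gs is fitted by double centering. The raw
residual variance s_g² = Σ_s r_gs²/(n−1) is biased: the other genes'
noise leaks through the per-sample means, with E[s_g²] =
((G−2)/G)σ_g² + (Σ_h σ_h²)/G². Inverting this gives the unbiased
estimator σ̂_g² = (G/(G−2))(s_g² − T̂/G²) with T̂ = (G/(G−1)) Σ_h s_h²;
negative estimates truncate at 0 before the square root is reported.
G ≥ 3 is required for the correction to exist.

The grouped variant (explicit opt-in via `groups=`) follows the
model-based grouped formulation: per-group intragroup variances v_ig by
the same estimator, double-centered group-mean deviations d_ig shrunk by
γ̂²/(γ̂² + v_ig/n_g) with γ̂² = max(0, Σd²/((G−1)(K−1)) − mean(v/n)),
and stability = mean over groups of |d̃_ig| + √(v_ig/n_g). Ungrouped is
the default because the study design this package emulates analysed
strata as small as one condition (n = 4, no grouping possible) and did
not state group use elsewhere; the two variants genuinely differ and
neither can be asserted as "the" published one.

**Ct dispersion (BestKeeper).** The reported SD[±Ct] follows the
original applet: the mean absolute deviation of Ct from the gene's
arithmetic mean (default dialect); the conventional sample SD is
available via `dialect="sd"`. The ranking uses dispersion only. The
BestKeeper index (per-sample geometric mean of Ct across genes) and each
gene's Pearson correlation with it are computed as descriptives; a
constant gene has undefined correlation (reported absent with a warning)
but still ranks best on SD = 0. CV[%] = 100·SD/mean.

**Comparative ΔCt.** S_g = mean over partners h of SD_s(Ct_gs − Ct_hs).
With E = 2 for all genes this coincides numerically with the M-value's
per-pair SDs; the two algorithms still rank differently because the
stepwise procedure re-averages after each exclusion.

Invariances (asserted in tests): adding a constant to one gene's Ct row
changes none of the four values; adding a constant to one sample's
column (all genes) changes none of geNorm/ΔCt/NormFinder — BestKeeper's
dispersion is deliberately not invariant to sample-wise shifts, since it
operates on raw Ct.

## Consensus

Per algorithm, stability values map to ascending competition ("min")
ranks computed on unrounded values; the stepwise algorithm contributes
its structural ranks directly. The consensus value per gene is the
geometric mean of its ranks across the four algorithms (fixed order:
ΔCt, BestKeeper, NormFinder, geNorm) and the final order sorts
ascending. Competition ranking with rank skipping is required for
consistency with the tied-pair-then-rank-3 semantics of the stepwise
column. Equal geomeans are broken alphabetically for deterministic
output and flagged (`tied_geomean`); the aggregation is invariant to any
order-preserving transform of each algorithm's values.

## Normalizer impact (ΔΔCt)

For donor d and condition pair (num, ref): ΔCt_c = Ct_target,c −
Ct_hkg,c and FC = E^−(ΔCt_num − ΔCt_ref), one value per donor from
single paired samples (no replicate averaging, matching an n = 4
design). The W/B ratio FC_worst/FC_best satisfies W/B = E^(ΔW − ΔB)
where Δ· is each normalizer's own between-condition Ct difference — the
artifact depends only on the reference genes' behaviour, never on the
target. Ratios ≥ 2 are flagged (threshold configurable).

Merged-donor significance uses a two-sided one-sample t-test of the raw
fold changes against the hypothetical mean 1 (t = (mean−1)/(SD/√n),
df = n−1), exactly as the emulated study specifies, even though testing
log2 FC against 0 is statistically preferable — the log-scale variant is
provided behind `log_scale=True` and is not the default. Degenerate
zero-SD inputs: mean = 1 gives t = 0, p = 1; mean ≠ 1 reports p = 0
with a warning. Significance tiers: ns / * / ** / *** / **** at 0.05 /
0.01 / 0.001 / 0.0001. Because the study convention leaves the merged
display scale ambiguous, both the arithmetic and the geometric mean FC
are reported; the t-test always uses the per-donor raw FCs.

## Synthetic data generator

Ct_gs = baseline_g + shift_{c(s),g} + donor_d(s) + ε_gs with
ε ~ N(0, σ_g) and donor offsets ~ N(0, σ_donor) shared across all of a
donor's samples and genes. Gaussian noise on the cycle scale (log-normal
expression noise) is the standard qPCR error model; a scaled Student-t
option (dof 3 by default) provides heavier tails for robustness checks.
Condition shifts are additive in Ct, hence multiplicative in expression,
so planted target effects obey ΔΔCt algebra exactly: a target with log2
fold change f in condition c is shifted by −f cycles.

Defaults (`default_study_config`) emulate the reference study design:
5 HKGs × 3 conditions (FBS, X1, X2) × 4 donors = 12 samples. HKG
baselines are the design's reported all-condition mean Ct values (ACTB
12.72, EF1A 10.19, GAPDH 11.42, RPLP0 11.07, TBP 20.51) and the
per-condition shifts are the reported condition means minus those
baselines (a few tenths of a cycle). The remaining parameters are not
published and were fixed once at plausible values: donor offset SD 0.3
Ct and per-gene noise SD 0.3 Ct (consistent with the reported
between-sample SEMs of roughly 0.1–0.4 Ct at n = 4–12); target baselines
LIF 16, CCL5 18, IL6 14 Ct; target condition effects relative to FBS of
log2 FC −1/−1.2 (LIF), +0.5/+0.5 (CCL5) and −2/−2.5 (IL6) in X1/X2, a
strong IL6 reduction with a mild CCL5 increase.

What the generator does *not* emulate: amplification-efficiency
variation, technical-replicate structure, preamplification bias,
gene-specific donor interactions, and any correlation structure among
HKG noise terms. Passing recovery tests therefore demonstrates that the
algorithms and pipeline are implemented correctly under the declared
model, not that the algorithms are robust to those real-data features.

`spiked_instability` scales one gene's noise SD (multiplier ≥ 1) to
plant a detectably unstable gene; with a 5× spike on a 0.3-Ct background
all four algorithms place the spiked gene last in ≥ 95% of seeded
replicates, the concordant-detection property the consensus rests on.

## Orchestration and numerical conventions

The study-preset stratification is: each condition, each condition pair,
all conditions, and each donor (11 strata for a 3-condition × 4-donor
design). Strata failing an algorithm's arity precondition (G < 3 for the
stepwise and model-based algorithms) are logged and skipped without
aborting the run. Reports print 2 decimals, as ranking tables
conventionally do; JSON outputs retain full precision. Runs are
deterministic given the input and seed — byte-identical output files.

Problem sizes used by the test suite and benchmark script: oracle
equivalence on 100 random 4–6 × 4–12 matrices (tolerance 1e−10);
parameter recovery averaged over 500 replicates at n = 100 samples
(within 10%); spike concordance over 200 replicates; rank-uniformity
goodness-of-fit over 400 replicates (α = 0.01). These sizes give Monte
Carlo error comfortably below each assertion's tolerance.

## Known limitations

- The stepwise exclusion and the consensus tie-break are deterministic
  conventions; other tools may order exact ties differently.
- The published consensus tables this package cross-checks against rank
  on unrounded values; printed two-decimal ties between distinct genes
  cannot be disambiguated from the tables alone (the bundled fixture
  stores orderings, not values, for that reason).
- BestKeeper's index correlations are reported but do not enter the
  ranking; tools differ on this point.
- The one-sample t-test on raw fold changes inherits the asymmetry of
  the ratio scale; use the log-scale variant for inference you intend to
  defend.
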