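# Methods

This note documents the statistical models, numerical choices and known
limitations of `refstab`. Lower stability values mean more stable genes in
every method.

## Data model and missing values

Cq measurements are kept tidy: one record per (sample, gene, technical
replicate), with condition and biological replicate attached to the sample.
A Cq must lie in (0, max_cycles] (default 40, configurable per instrument);
a well that never crossed the threshold is an explicit missing entry, not
an error. Technical replicates are arithmetically averaged before any
statistic is computed, matching standard practice.

Missing entries are excluded *pairwise*: each pairwise statistic (ΔCt SDs,
geNorm ratios, BestKeeper correlations) uses the samples where both genes
are present, and a pair sharing fewer than two samples is dropped with a
warning. NormFinder is the exception — its two-way model needs complete
rows, so incomplete samples are dropped with a warning. Rationale: listwise
deletion would discard usable samples from statistics that never needed
them.

## Relative quantities

geNorm and NormFinder operate on relative quantities
Q[s,g] = E_g^(Cq_min,g − Cq[s,g]), so each gene's maximum Q is 1 and
log2(Q) is finite. The default efficiency is E = 2 for every gene (perfect
doubling — the assumption baked into the classical stability tools);
per-gene estimates can be supplied instead. E ≤ 1 is rejected: it would
make "more template" mean "later Cq" meaningless.

## The four stability statistics

**Comparative ΔCt.** For each ordered pair (j,k), d_i = Cq[i,j] − Cq[i,k];
stability(j) = mean over k≠j of the n−1 SD of d. Invariant to per-sample
loading shifts (a shift enters both genes and cancels).

**geNorm.** M_j = mean over k≠j of SD_i(log2(Q_ij/Q_ik)). The stepwise
ranking recomputes M on the remaining subset and excludes the argmax until
two genes remain; those two are mutually indistinguishable by M (for a
2-gene subset M_1 = M_2 by construction) and share the tied rank 1.5 under
the package-wide average-tie convention. A tie at the maximum M is broken
by excluding the gene later in input order, and is logged. Pairwise
variation V_{n/n+1} is the n−1 SD over samples of
log2(NF_n/NF_{n+1}), NF_n being the geometric mean quantity of the top-n
genes.

**BestKeeper.** Works on raw Cq by design: geometric and arithmetic means,
min, max, SD [±CP] and CV [%CP]. SD [±CP] is implemented as the mean
absolute deviation of Cq about the *geometric* mean (the original tool's
convention; `use_classical_sd=True` switches to the n−1 SD about the
arithmetic mean). The BestKeeper index is the per-sample geometric mean of
Cq across genes; each gene's Pearson r against the index is reported as an
extra, not used for ranking. Because it never leaves the Cq scale,
BestKeeper responds to loading differences — the test suite asserts this
non-invariance explicitly, alongside the invariance of the other three.

**NormFinder.** On y = log2(Q), the additive model
y[i,g] = gene effect + sample effect + ε[i,g], Var(ε[i,g]) = σ²_g. With z
the sample-centred values and s²_g their per-gene n−1 variance,
E[s²_g] = σ²_g(1 − 2/k) + S/k², S = Σσ²_h. Solving the moment equations
gives Ŝ = k/(k−1)·Σs²_g and σ̂²_g = k/(k−2)·(s²_g − Ŝ/k²), floored at 0
(flooring is logged); stability = √σ̂²_g. At least 3 genes are required —
with k = 2 the correction factor diverges and the decomposition is not
identifiable. The grouped variant (off by default; the analyses this
package targets rarely declare groups) estimates per-group variances the
same way, centres per-gene group means across groups into intergroup
differences d_ag, shrinks them by γ̂²/(γ̂² + σ̂²_ag/n_a) with
γ̂² = max(0, mean(d²) − mean(σ̂²/n)), and reports
mean_a(|d̂_ag| + √(σ̂²_ag/n_a)).

## Consensus ranking

Ranks, not raw values, are aggregated: the four methods live on
incompatible scales (cycles, log2 units, model units) while ranks are
directly comparable — and aggregation of ranks by plain geometric mean is
the published behaviour of the popular consensus tool. Within each method
ties receive the average of their positions, so the geometric mean is
always well defined. The final order is ascending in the geometric mean;
ties break by mean method rank, then input gene order. Display values are
rounded half-up to 2 decimals (matching how such tables are typeset);
full-precision values are always carried alongside.

## Amplification efficiency

Two conventions coexist deliberately. Per-well: E = 10^slope of
log10(fluorescence) vs cycle inside a window-of-linearity — what
curve-analysis software computes from raw plates. Dilution series:
E = 10^(−1/slope) of Cq vs log10(dilution). The per-well estimator is the
default; both are exposed, and the discrepancy between the conventions is
documented rather than silently resolved.

The per-well pipeline:

1. **Baseline correction.** A constant background b ∈ [0, min early-cycle F]
   is sought that maximises the best window's R² of log10(F − b) vs cycle.
   Numerics required two refinements of the plain search. First, the search
   objective evaluates the *longest* eligible window (final window length
   + 4): over only 4–6 points, a residual baseline can cancel plateau
   curvature and look spuriously log-linear, biasing E low on noisy wells;
   a longer span breaks that degeneracy. Second, because 1 − R² of the best
   window reaches machine precision while b is still wrong at the scale of
   the faintest window points, a bounded Brent polish re-optimises b on the
   finally selected window with an x-tolerance proportional to that
   window's minimum fluorescence. Verified on generator output: noise-free
   recovery error ≤ 5e-8 across E ∈ [1.5, 2.3]; with a realistic constant
   background the closed loop is accurate to ~1e-5.
2. **Window of linearity.** The contiguous window of 4–6 cycles (both
   configurable), strictly positive and below 0.8 × max fluorescence (a
   simple, testable proxy for plateau detection), maximising R²; ties go to
   the earlier, then longer, window.
3. **Regression.** E = 10^slope; a non-positive slope rejects the well.
   Per amplicon, the mean and n−1 SD over accepted wells are reported;
   wells outside an acceptance range (default 1.5–2.3) are flagged and kept
   unless exclusion is requested; a quality flag marks mean E outside the
   conventional ideal band [1.8, 2.0] or mean regression r < 0.995. The
   reported r is the mean per-well regression correlation, labelled as
   such.

Flat curves (max fluorescence < 5× the early-cycle median) are reported as
no-amplification and excluded. Baseline identifiability has a genuine
limit: if a curve spans many decades above the analysis window (no plateau
within the recorded cycles), the best-window R² objective saturates and the
background is only weakly determined; real plateauing curves do not hit
this.

## 2^−ΔΔCt quantification

ΔCt = Cq_target − Cq_ref per biological replicate (multiple references:
arithmetic mean of their Cq values, i.e. normalising to the geometric mean
of their quantities); ΔΔCt subtracts the calibrator condition's mean ΔCt;
RQ = 2^−ΔΔCt. RQ is computed per replicate and then summarised as
mean ± SE — so the calibrator's mean RQ is ≈1, exactly 1 only under
`average_before_exponentiation=True` (which exponentiates the mean ΔΔCt
instead). Efficiency-corrected ratios are not the default — the classical
method assumes E = 2 — but per-gene efficiencies can be supplied for
sensitivity analysis, in which case each gene's Cq is scaled by log2(E)
before differencing. `expression_profile` repeats the calculation once per
candidate reference in consensus order, the standard way to show how the
choice of normaliser distorts a target's apparent response.

## Synthetic data: what it emulates, what it does not

`simulate_cq` draws
Cq[s,g,r] = baseline_g + effect[condition(s), g] + load_s + ε, with
ε ~ N(0, σ_tech²), load_s ~ N(0, σ_load²) shared by all genes of a sample,
and condition effects ~ N(0, τ²) drawn once per run and held fixed across
replicates — a treatment effect, the very instability the methods measure.
Designed-stable genes and the control condition have exactly zero effect.
Noise is normal on the Cq (log-quantity) scale, the standard qPCR error
model. Defaults mirror a typical validation design: 9 candidates,
4 conditions (control + 3 levels/timepoints), 3 biological × 2 technical
replicates, baselines uniform in 20–34 cycles, σ_tech = 0.15,
σ_load = 0.5, τ = 1.0 cycles, per-amplicon efficiencies uniform in
1.90–2.07.

`simulate_curves` builds raw traces F(c) = baseline_f + A(c) with
A(c) = F0·E^c/(1 + F0·E^c/F_max) and F0 anchored so the noise-free curve
crosses the threshold at the intended Cq (within 0.05 cycles).
Defaults: threshold 0.2, background 2.0, plateau 2000 fluorescence units —
plateau ≈ 10⁴ × threshold and background ≈ 10⁻³ × plateau, typical
instrument ratios. Multiplicative noise applies to the amplicon signal
only, not the constant background: dye signal scales with product amount
while background fluorescence is comparatively stable.

Not emulated: per-cycle efficiency decline, inter-run batch effects,
melting behaviour, correlated co-regulation between candidate genes. A
green recovery test therefore establishes that the statistics identify
designed-stable genes under independent treatment shifts and Gaussian
noise — not that they are robust to co-regulated panels, which is a known
blind spot of all four methods (a gene tracking the panel-average drift
scores as stable, particularly under NormFinder's mean-referenced model).

`recovery_experiment` quantifies this: across seeded replicate worlds it
tallies how often designed-stable genes reach the top-k per method and in
consensus. Under the defaults, both designed-stable genes occupy the top-2
consensus positions in roughly 80% of runs; failures trace to unstable
genes that happen to draw near-zero (or panel-average) effect profiles —
an inherent feature of the simulated world, not an estimator defect (the
estimators match brute-force oracles to 1e-12 in the test suite).

## Numerical conventions

- SDs use the n−1 denominator throughout; CV% = 100·SD/mean.
- Ranks use average ties; exact ties in geNorm's stepwise exclusion break
  toward the later input gene (logged).
- Geometric means are computed in log space.
- Display rounding is decimal half-up at 2 dp; comparisons in tests use
  |diff| ≤ 0.005 at that precision.
- All simulation randomness flows through `numpy.random.default_rng`
  seeded from the configuration; the pipeline's CSV outputs are
  byte-identical across reruns with the same inputs and seed.
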