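# Methods

This note documents the models and procedures implemented in `coopnet`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Conventions

All genomic intervals are 0-based half-open (BED-native); the only interval
input is BED, so nothing is converted. Expression values are assumed to be on
the log2 scale (the convention of RMA-normalised arrays); fold changes are
therefore differences of group means. Peaks carry the peak caller's posterior
probability; the significance filter keeps peaks with posterior strictly
greater than 0.9, and peaks read from score-less BED default to posterior 1.0
so pre-filtered inputs pass through.

## Peak-to-gene annotation

A peak is assigned to the nearest TSS within ±20 kb, measured from the peak
midpoint `⌊(start+end)/2⌋`, unstranded — the midpoint is the conventional
single-point summary and strand does not change the absolute distance. A
nearest-TSS-within-a-window rule leaves midpoint vs any-overlap open;
midpoint was chosen and is flagged here for users.
Equidistant TSSs resolve to the lexicographically smallest gene id so output
is deterministic. Promoter binding uses a ±500 bp window around the TSS with
≥1 bp overlap counting as bound.

Library QC correlates log2(read count + 1) between ChIP libraries (Pearson)
and orders them by average-linkage clustering on 1 − r.

## PWMs and scanning

TRANSFAC count matrices are column-sum normalised, then a pseudocount of 0.01
is added to each probability and rows are renormalised; this keeps log-odds
finite without visibly distorting informative positions. Scores are log2
odds against a background (default uniform); `N` contributes 0 bits. A
sequence "contains" a motif when its best hit reaches 70% of the PWM's
maximum achievable score — a dialect-independent rule, configurable, chosen
because count- and probability-derived PWMs put the same consensus sites
above it. Both strands are always scanned; ties break to the smaller offset,
then the + strand.

## Spaced-motif enrichment

Sequences are centred and oriented on the primary motif's best hit;
sequences whose ±50 bp margins would truncate at an edge are dropped and
counted. For each secondary motif, every surviving sequence contributes the
best secondary site in the margins regardless of score (thresholding is
available but off by default, so weak but consistently spaced sites still
count). Bins are (gap in bp at 1 bp granularity) × (same/opposite strand ×
left/right side); the bin count is tested against `Binomial(n, 1/n_bins)`
and Bonferroni-adjusted over `n_bins × n_secondary_motifs`.

Two behaviours deserve emphasis:

- **Score ties are resolved uniformly at random (seeded).** Near-consensus
  PWMs score windows by match count, so dozens of windows tie; any
  deterministic tie rule (e.g. smallest gap) funnels those ties into
  specific bins and breaks the uniform-bin null badly — in null simulations
  a min-gap rule produced adjusted p < 0.05 in 16/20 seeds, the random rule
  in 0/20. The deterministic rule remains available (`tie_break="min-gap"`).
- **Palindromic primaries halve the quadrant resolution.** TRE and CRE are
  their own reverse complements, so the orientation of the primary site is
  arbitrary and a partner planted same-strand-right is recovered in the
  equivalent {same-strand-right, opposite-left} bin pair. Gaps are
  unaffected. For non-palindromic primaries the full four-quadrant geometry
  is identifiable, and reverse-complementing every input leaves all counts
  unchanged.

## Cooperativity test

For TFs A and B with promoter-binding indicators, gene pairs are formed
within the both-bound set (P_both) and within each single-bound set
(P_single); cross-class pairs are excluded — the cleanest reading of
"both-bound targets more correlated than targets of either TF alone". All
N = |P_both| + |P_single| pairs are ranked by Pearson correlation across the
samples of one condition (Spearman by flag), ties broken by lexicographic
pair id, and the top k = ⌈0.05·N⌉ pairs are tested: the count of both-bound
pairs among them is hypergeometric under the null (the marginal of the
three-class multivariate hypergeometric), and the upper tail is the p-value.
The 5% cut is exposed as `top_fraction`; the rank-quantile form was chosen
over a correlation-value threshold because it is invariant to monotone
transformations of the correlations. Degenerate inputs (fewer than two
both-bound genes) return p = 1 with a flag rather than an error, matching
the "no binding sites observed" reporting convention of the partner screen.

## Latent-force target ranking

Model: `dx/dt = B + S f(t) − D x`, `x(0) = x0`, with `f ~ GP(0, exp(−(t−t')²/l²))`.
The output is then a GP with mean `B/D + (x0 − B/D)e^{−Dt}` and covariance

    k_xx(t,t') = S² (√π l / 2) [h(t,t') + h(t',t)]

in error functions (the classic analytic form for a first-order ODE driven
by an RBF GP), plus the cross term `k_xf`. All `exp(γ²)·erf(·)` products are
evaluated through `erfcx` so no exponent that reaches `exp` is positive;
the implementation agrees with a double-quadrature oracle to better than
1e-6 relative everywhere tested and yields positive semidefinite Gram
matrices (jitter 1e-8 on diagonals).

The TF's own mRNA profile is treated as a noisy direct observation of `f`
(no protein-translation stage — the simplest variant consistent with the
framework); it is centred by its sample mean, and the reported basal rate is
mapped back to the raw force scale (`B = B_fit − S·mean(f_obs)`, exact for a
constant shift). Replicates are repeated observations of one latent
trajectory with independent noise, never averaged. Hyperparameters
(B, x0, S, D, gene noise σ², length-scale l, TF noise σ_f²) are estimated by
maximising the joint log marginal likelihood from a deterministic multi-start
grid (D ∈ {0.1, 0.5, 1.5}/h, l ∈ {1, 2, 4} h, S ∈ {0.5, 2}); the two best
grid points are refined by L-BFGS-B (≤40 iterations). σ_f² is a free
hyperparameter: moment estimates from successive differences absorb signal
slope on coarsely sampled pulses and biased B upward by ~20%.

The null model clamps S = 0, under which the joint likelihood decomposes
into the TF block (optimised once per TF profile and reused across genes)
plus an iid Gaussian around the homogeneous ODE mean. Genes are ranked by
`score = ll_alt − ll_null`; the ratio is scale-free across genes, unlike the
raw likelihood, which also reflects each gene's noise level (`ll_alt` is
still reported). The null being nested, `ll_alt` is floored at `ll_null`.

## SAM differential expression

`d = (mean₂ − mean₁)/(s + s₀)` with `s` the pooled standard error and `s₀`
the percentile of the `s` distribution (grid 0, 5, …, 100) minimising the
coefficient of variation of window-median |d| across s-quantile windows.
The null is two-class label permutation: with the 4+4 design all C(8,4) = 70
assignments are enumerated (deterministic q); otherwise 200 seeded draws.
For each gene's |d| threshold, estimated false calls are the median
permutation exceedance count (median, not mean, per SAM convention) divided
by observed calls; q is then made monotone (step-up) so a larger |d| never
has a larger q. No π₀ correction is applied, which is conservative. Genes
with q ≤ 0.05 split into up/down by the sign of the mean difference.

## Enrichment

GSEA-preranked uses the weighted KS running sum (hits += |metric|^p
normalised over the set, misses −= 1/(N − N_H)); ES is the signed extreme.
The null is random same-size gene sets — the only valid null for a
preranked metric — with sign-stratified NES and FWER from the permutation
distribution of the maximum |NES| over the collection. Default weight p = 1
matches the classic statistic, but the *pipeline* calls it with p = 0: the
likelihood-ratio metric is zero-inflated (non-targets pile at score 0), and
with p = 1 a random set containing a single high-score gene saturates the
running sum, so true and random sets become indistinguishable (observed
null ES ≈ true ES ≈ 0.85). With p = 0 planted target sets reach NES ≈ 5 and
FWER 0 while null calibration is preserved.

Over-representation is the hypergeometric upper tail on the 2×2 table of
set membership × DE membership within the expression-matrix universe, run
separately for up- and down-regulated genes; odds ratios use a Haldane 0.5
correction when a cell is zero.

## Network assembly

Partner TFs must pass both the spacing test (Bonferroni-adjusted p < 0.01)
and GSEA (FWER < 0.05); the retained sets' member union forms the target
layer (deduplicated — a gene in two sets is one node with two edges), with
per-gene DE direction attached. The Fisher result is carried as edge
evidence, not a retention filter.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
peak sequences with one primary site (TRE or CRE) and partner sites at fixed
gap/quadrant in a configurable fraction of peaks; a 0/2/4/8 h × 4-replicate
two-condition design in which the second condition's TF force is scaled by
1/20; target genes integrated through the linear ODE (trapezoid on an
801-point grid) with Gaussian noise (sd 0.25, the log2-microarray regime);
flat non-targets; and optional gene blocks sharing a standardised latent
profile to pin within-block correlation exactly at its nominal value.
Planted motif sites are sampled from the consensus positions of the PWM
(degenerate positions uniform over their allowed bases); full-PWM sampling
is available but mutates ~25% of 9–10 bp sites below any sensible presence
threshold, which would conflate generator noise with pipeline recovery.
The TF activity pulse `A(t/2)e^{1−t/2}` (rise by 2 h, decay by 8 h) is fixed
rather than random so ranking results vary only through observation noise.

Not emulated: read-level ChIP-seq (coverage, fragment-length effects, peak
caller artefacts), probe effects and normalisation residue on arrays,
sequence composition bias (background is uniform ACGT), TF protein dynamics
(the mRNA profile stands in for activity), and overlapping/nested gene
structures. Passing tests therefore demonstrate correctness of the
statistics and recovery of planted structure under the model's own
assumptions, not robustness to these real-data complications.

The bundled end-to-end scenario plants 5 partner motifs and 120 target
genes among 600 (~300 peaks). The target fraction (20%) mirrors the
motivating study's proportion of network targets on a genome-wide array; in
a universe where targets are the majority, set-level enrichment against the
ranking is undetectable in principle, so smaller universes are not useful
test beds for the GSEA stage.

## Problem sizes and run times

Defaults were sized so the full test suite and the acceptance script each
run comfortably on a single CPU: calibration checks use 500 null datasets
(cooperativity), 20 null seeds (spacing), 50 seeds (SAM), 6 seeds × 10 sets
(GSEA); the ranking benchmark scores 200 genes and the end-to-end scenario
600. One latent-force fit takes ~0.3 s; a full pipeline run on the bundled
scenario takes 3–4 minutes, dominated by the per-gene GP fits.

## Known limitations

- Quadrant identity is unresolvable for palindromic primaries (above).
- The spacing null assumes bins are equiprobable; strong composition bias
  in real peaks would make it anticonservative. SpaMo-style redundant-
  sequence collapse is not implemented.
- The cooperativity test conditions on the binding matrix; errors in motif
  presence calls propagate into the gene classes.
- The GP fit uses a small multi-start grid and bounded hyperparameters
  (D ∈ [0.01, 8]/h, l ∈ [0.3, 8] h); profiles far outside the 0–8 h regime
  would need wider grids.
- Mapping TRANSFAC matrix ids to unique TF names is left to a user-supplied
  table; the package reports per-matrix results.
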