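# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `regmeth`. It is written for
users who want to know precisely what each stage computes and what passing
the test suite does and does not demonstrate about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open. The Bismark coverage
format (1-based inclusive) is converted at the I/O boundary; BED is taken
verbatim. A CpG site is addressed by the + strand position of its cytosine;
strand is not tracked past methylation extraction. Region sets are kept as
downloaded — internal overlaps are never merged. Duplicate CpG records in
one coverage file are rejected rather than summed, since a well-formed
extraction emits each cytosine once.

## Beta-binomial differential methylation

For sample i at one CpG, the methylated count is modeled as
m_i ~ BetaBinomial(n_i, μ, φ) with mean μ and dispersion φ, parameterized
through Beta(α, β) with α = μ(1−φ)/φ, β = (1−μ)(1−φ)/φ; the variance of
m_i is n_i μ(1−μ)(1 + (n_i−1)φ).

**Smoothing.** Group methylation levels are estimated from pooled counts
summed over all CpGs of the same chromosome within ± window/2 of the site
(default window 300 bp, targeted and WGBS modes alike). Pooling is per
group over pooled per-sample counts; when the window is smaller than the
inter-CpG spacing, smoothing reduces to the per-site fraction.

**Variance.** Because beta draws are independent across sites and
samples, the variance of the smoothed pooled count is the window-sum over
sites of Σ_i n_i(1 + (n_i−1)φ) · μ(1−μ), and

Var(μ̂_g) = μ_g(1−μ_g) · W_g / N_g²,  W_g = window-pooled Σ_i n_i(1+(n_i−1)φ_i),

with N_g the pooled smoothed depth. The overdispersion factor is applied
at the site level *before* pooling; applying it to the pooled depth would
overstate the variance roughly k-fold for k sites per window.

**Dispersion estimation.** Per site, a method-of-moments estimate from
replicate fractions: with s² the sample variance of the observed fractions
and E[1/n] the mean reciprocal depth over informative replicates,
φ̂ = (s²/(μ̂(1−μ̂)) − E[1/n]) / (1 − E[1/n]), floored at 10⁻⁴ and capped at
0.5, then shrunk toward the chromosome-wide median with weight 1/(1+k)
for k informative replicates. A group without ≥ 2 informative replicates
borrows the other group's estimate; one-vs-baseline comparisons use the
baseline group's dispersion for both sides (`dispersion_from`), since a
single sample cannot inform φ.

**Calling.** A site is tested only if the unsmoothed pooled depth reaches
the mode's minimum in every group. With diff = μ̂_a − μ̂_b and
se² = Var(μ̂_a) + Var(μ̂_b): the Wald statistic diff/se gives a two-sided
normal p; the posterior probability that the true |difference| exceeds the
practical threshold δ is approximated by Φ((|diff|−δ)/se); a DMC requires
both |diff| > δ and posterior probability above the mode's cutoff.
Presets: targeted — depth 6, δ 0.2, pp 0.99999; whole-genome — depth 2,
δ 0.1, pp 0.99. Only autosomes are tested; the chromosome filter is
configurable. Group means use pooled smoothed counts rather than means of
per-sample fractions, which is robust at low per-sample depth.

**DMRs.** Runs of consecutive tested CpGs with p < threshold (default
0.01) and a common direction, broken by any non-qualifying CpG, by a
direction change, or by a gap > max_gap (default 100 bp — the merge
distance is otherwise unspecified, so it is exposed in config). Emitted
runs need ≥ 3 CpGs and ≥ 50 bp first-to-last span (half-open).

**Per-sample counts.** Each sample is compared alone against the pooled
baseline panel (common dispersion from the baseline); significant hyper
and hypo counts are scaled to counts per million tested CpGs.

## Region-set enrichment

Membership is point-in-interval against the tested-CpG universe; a CpG
under several overlapping intervals of one track counts once. The 2×2
table (a = query∩track, b, c, d) gets a one-sided enrichment p from the
hypergeometric upper tail P(X ≥ a); the odds ratio (a·d)/(b·c) applies the
Haldane–Anscombe +0.5 to all cells iff any cell is zero. BH correction is
per supplied track batch; hyper- and hypomethylated queries are tested
separately against the shared universe.

## Cell-type-specific open chromatin

Counts are CPM-normalized per sample. Each (peak, type) pair is tested
with a one-sided Wilcoxon rank-sum of the type's samples against all other
samples (exact enumeration when min(n₁,n₂) ≤ 10 and tie-free, otherwise
normal approximation with tie correction and continuity correction). BH is
pooled across all peak × type hypotheses — the stricter and
simpler-to-specify scope — and assignment is non-exclusive. Note that the
focal-vs-all-others design dilutes the test for a peak open in several
types; such peaks need a lenient FDR or larger replication to be assigned
to all of them.

## Motif scanning

log₂-odds scores: logodds[i,b] = log₂((counts[i,b] + pc·bg_b)/(total_i +
pc)) − log₂ bg_b, with background-proportional pseudocount pc (default
0.8) and uniform background by default. The p-value → score threshold is
the smallest t with P(score(W) ≥ t) ≤ p for a random i.i.d. background
word W, computed by convolving discretized per-column score distributions.
The internal grid is `width` times finer than the nominal bin count
(default 10⁴ bins over the score span) so the accumulated rounding error
stays under half a nominal bin; FFT convolution keeps this fast. When even
the maximum score has tail mass above the cutoff, the maximum score is
returned with a flag. Scanning applies max(p-value threshold, absolute
score cutoff) — both constraints active — on both strands, reporting minus
-strand hits in + coordinates; windows containing N are skipped; the
score-cutoff unit is log₂ (a config switch, since log-base conventions
differ between tools). Overlapping matches are all reported.

## Motif-repositioning permutation test

The statistic t_obs is the unweighted mean of per-region methylation
differences Δ(region) over the distinct regions fully containing ≥ 1
match; Δ(region) is mean-of-carrier minus mean-of-control per-sample
region means (CpGs with depth ≥ 6), cached across permutations. Each
permutation independently repositions every match: a region is drawn with
probability proportional to its number of valid starts (length − width
+ 1), then a start uniformly; overlaps among repositioned matches are
allowed. Empirical one-sided p = #{t_perm > t_obs}/n_perm (strict
inequality); a Phipson–Smyth add-one p ((b+1)/(n+1) with b = #{t_perm ≥
t_obs}) is reported alongside, and the two-sided variant is
min(1, 2·min(#{>}/n, #{<}/n)). Per-test RNG streams are derived by hashing
(seed, motif, cell type), so results are independent of iteration order.

**Calibration.** Under the test's own null — match positions random
within the regions and no group effect — the observed statistic is
exchangeable with the null draws and the p-value is uniform; the test
suite verifies the 0.05-level rejection rate over 500 replicate datasets.
When the observed matches are more structured than the null (e.g. at most
one motif per region, as in the generator's planted placements), the
with-replacement null spreads over fewer distinct regions and is slightly
over-dispersed, making the test conservative — never anticonservative.

## Correlation inference

Pearson r; t = r√(df/(1−r²)) with df = n−2 and a two-sided t p-value;
95% CI tanh(atanh r ± 1.959964/√(n−3)), following R's `cor.test`. At
|r| = 1 the interval collapses to the point rather than crashing. The
cohort-comparison analysis forms, per (motif, cell type), the methylation
change at motif-bearing open chromatin *relative to* all open chromatin of
that type; "relative" is implemented as a difference by default (ratios
are unstable when the denominator change is near 0 and the sign semantics
survive differencing), with `relative="ratio"` available. The
signal-vs-methylation analysis filters units (CpG islands) to average
wild-type signal ≥ 10 before testing.

## Synthetic-data generator

The generator emulates the study's input structure, not its biology:

- **Genome.** Chromosomes (default 2 × 100 kb) with equally spaced
  open-chromatin peaks (200 peaks of 300 bp, round-robin over 4 cell
  types) in the first 70%, a heterochromatin-like block in the last 25%,
  and background in between. CpG dinucleotides are written at the
  configured density (default 10/kb; placement jitter configurable),
  avoiding motif footprints.
- **Motifs.** Consensus sequences (not PWM samples) of sharply peaked
  built-in PFMs are embedded on random strands inside a configurable
  fraction (default 0.5) of each type's peaks — consensus planting
  guarantees recoverability above any sensible threshold, making scan
  tests deterministic.
- **Methylation.** Depths are Poisson (mean 30; only minimum-coverage
  filters, not depth distributions, are known for the real data), and
  counts beta-binomial with region-class baselines (enhancer 0.2,
  heterochromatin 0.8, background 0.5) and dispersion φ = 0.05 by default
  (no cohort dispersion estimates exist to copy; exposed in config).
  Carriers receive signed shifts (default 0.3, 97.6% positive) at the
  planted CpGs, chosen per scope: motif-bearing peaks of one cell type,
  all peaks of a type, a contiguous block, or genome-wide; signs can be
  drawn per site or coherently per region.
- **ATAC.** Negative-binomial fragment counts (mean 50, dispersion 0.1),
  10-fold elevated at a peak in samples of its specific cell type.
- **Determinism.** All streams derive from `SeedSequence(seed,
  spawn_key)`; identical configs are byte-identical across platforms.

The cohort defaults — 5 carriers vs 10 controls, 2,000 CpGs, 200 regions —
mirror the study's comparison sizes at desk scale.

**What passing tests shows.** Recovery and calibration results on this
generator validate the *inference machinery* under the model it assumes
(beta-binomial counts, independent sites, uniform motif placement). Real
bisulfite data violate several of these: correlated methylation of
neighboring CpGs beyond window sharing, cell-composition confounding,
non-Poisson coverage, GC- and mappability-biased peaks, and motif matches
that cluster in CpG-poor subregions. Passing here does not certify
performance under those violations.

**Chosen problem sizes.** The planted-recovery analysis uses a dense
targeted panel (50 CpG/kb, 20,000 CpGs, φ = 0.005, depth 30, 5v5) with a
contiguous block of 200 affected CpGs — a power analysis shows the
posterior-probability rule at δ = 0.2 needs se ≈ 0.017 to detect a 0.3
shift, which at depth 30 requires both replicate pooling and window
pooling over ~15 dense CpGs; isolated affected sites at sparse density are
intrinsically diluted by smoothing and would test the scenario, not the
caller. Calibration uses 500 replicate datasets at n_perm = 200; the
end-to-end run uses 1,000 permutations on the default cohort.

## Known limitations

- The DMC caller approximates the posterior probability by a normal tail,
  without hypothesis-specific variance shrinkage or the reference
  implementation's moving-average weighting; paired designs and covariates
  are out of scope.
- The enrichment module tests point queries only (CpG sites), not interval
  queries.
- Repositioning does not match GC or CpG composition of the original
  match positions; enrichment of methylation at motifs that prefer
  CpG-dense subregions can reflect composition rather than binding.
- The Wilcoxon exact regime switches to the normal approximation in the
  presence of any tie; CPM values from integer counts tie easily at low
  depth.
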