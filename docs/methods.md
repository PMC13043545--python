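# Methods

This note documents the models, defaults, and numerical choices behind
`toxscreen`, and what the synthetic-data generators do and do not emulate.

## Screen model and simulator

The simulator emulates a pooled loss-of-function screen with a minimal
two-guides-per-gene library. Baseline guide abundance aᵢ is log-normal
(σ = 0.5 by default, mean-normalized to 1) to mimic realistic library
skew while keeping `mean_depth` interpretable as fold-coverage. Control
cell means are μᵢ = depth·aᵢ; exposed means are μᵢ·2^λ(g(i)) where λ is
the gene's planted log₂ fold-change. Counts are negative binomial with
variance m + φm² (size r = 1/φ; φ = 0 is the Poisson limit). Defaults
reproduce the study design: 20,000 genes × 2 guides, 3 + 3 replicates,
400× coverage, φ = 0.05, 5% sensitive and 5% resistant genes at
|λ| = 1.5.

Effects are applied at the gene level — all guides of a gene share λ —
matching the loss-of-function interpretation; per-guide efficacy
variation, PCR/sequencing error, and copy-number artifacts are not
modeled. Simulated reads are single-end with the spacer at a fixed
offset in random context and constant quality (quality is never used);
consequently the FASTQ round-trip tests demonstrate correctness of the
exact-match counting path, not robustness to sequencing error.

## Guide quantification

Reads are matched by scanning every 20-nt window left to right against a
hash of library spacers; the first hit wins and a read increments at most
one guide. Exact matching (zero mismatches) keeps counts deterministic
and is the common default for spacer quantification; reverse-complement
rescanning is available by flag since library orientation is a dialect
decision. Per-sample accounting satisfies matched + unmatched = total.
Demultiplexing is assumed done upstream (one FASTQ per sample).

## Normalization and the guide test

Median-of-ratios normalization: reference = per-guide geometric mean over
rows with all counts positive; size factor = median ratio to the
reference; a total-count fallback (factors scaled to mean 1) covers
matrices with no all-positive row. Note that rescaling one sample's
column by k changes all normalized values by the common factor k^(1/S):
cross-sample structure, not absolute scale, is the invariant.

The mean–variance trend is fitted on control replicates: guides are
sorted by mean into 20 equal-occupancy bins, the excess variance (v − m)
is averaged within each bin over *all* guides, and a least-squares line
log(mean excess) = b₀ + b₁·log(mean m) over positive-excess bins gives
σ²(m) = m + e^{b₀} m^{b₁}, clamped to ≥ m(1 + 10⁻⁶). Averaging before
taking logs matters: with three replicates a per-guide log(v − m)
regression is biased low by Jensen's inequality and high by conditioning
on v > m; the binned fit recovers a planted φ = 0.1 within 10% and stays
within a few percent of σ² = m on Poisson data. With fewer than 30
over-dispersed guides, or fewer than 3 usable bins, a pooled
method-of-moments dispersion is used.

Each guide's evidence is the rounded mean exposed normalized count x
scored against NB(μ̂꜀, σ²). Zero control means are shifted by the
pseudocount (c₀ = 1, also used in log₂FC). Sizes above 10⁶ are evaluated
as Poisson (numerically equivalent and cleaner). Both one-sided tails are
kept; no two-sided p is produced, mirroring the sensitive/resistant split.

## Gene ranking (α-RRA) and calibration

Guides are ranked per direction (ties broken by guide id) and converted
to percentiles rank/M. A gene's score is the minimum Beta order-statistic
tail probability over its leading guides with percentile ≤ α = 0.25; if
no guide passes α the score is 1. The permutation null draws 100,000
pseudo-genes per guide-count class, sampling percentiles without
replacement from the pooled vector; p = (1 + #{ρ_perm ≤ ρ_obs})/(N + 1),
so the floor is 1/(N + 1) = 10⁻⁵ and p is stable at the 0.01 calling
threshold. BH-FDR is computed per direction but calling uses raw p, as in
the screen workflow this package reproduces.

A structural property worth knowing: under a fully null screen the gene
p-value distribution has an atom at 1 of mass (1 − α)^J (0.5625 for two
guides) — the genes whose guides all rank beyond the cutoff. Calibration
therefore holds on the informative component: p-values below the atom
are uniform after rescaling by 1 − (1 − α)^J, and the fraction of genes
below p = 0.01 is ≈ 1%. The tests assert exactly this.

Candidate calling uses strict inequalities: sensitive = p_low < 0.01 and
gene log₂FC < −0.6; resistant = p_high < 0.01 and log₂FC > 0.6, where the
gene log₂FC is the median of its guides' values (equal to the mean at two
guides; robust for more). Gene log₂FC sign makes the two calls mutually
exclusive.

## Disease over/under-representation

The universe defaults to the genes present in the annotation table; a
screened-gene universe can be supplied instead. Candidates outside the
universe are dropped and counted, so proportions stay in [0, 1]. One
shared collection of 1,000 random size-n subsets (uniform, without
replacement) is scored against every disease — cheaper than per-disease
redraws and it preserves the cross-disease correlation structure of the
null. z uses the sample SD (n − 1); p-values are one-sided per direction
with no multiple-testing correction, and 0.05 is the significance
threshold. Diseases with null SD = 0 (e.g. a term annotating the whole
universe) are flagged degenerate and excluded rather than given infinite
z. Reporting filters to observed proportion > 0.001 (strict) before
ranking by p, then |z|, then name, truncated to the top 15 per direction.

Sampling without replacement makes the exact null hypergeometric:
count ~ Hypergeom(N, K, n), mean proportion K/N, SD
√(n·(K/N)(1−K/N)(N−n)/(N−1))/n — the oracle used throughout the tests.

The annotation simulator plants true associations two ways. For
candidate-side planting, `construct_candidate_set` places
round(f·K/N·n) genes of each target disease into the set and fills the
remainder from genes un-annotated to any target, making the in-set
annotation rate f× baseline by construction — with f = 3, K = 200,
N = 20,000, n = 189 the planted z is ≈ 3 with little Monte-Carlo noise,
whereas planting by weighted sampling would make detection a coin flip at
this effect size (binomial noise on an expected count of ~6). For
annotation-side planting (used by the demo, where candidates come from
the actual screen), enriched diseases sample their gene sets with weight
f on a favored gene subset.

## Dose–response

Viabilities are vehicle-normalized, then fitted by nonlinear least
squares to v(c) = bottom + (top − bottom)/(1 + (c/ic50)^hill), initialized
at top = mean vehicle response, bottom = minimum per-concentration mean,
ic50 = geometric mean of positive doses, hill = 1, with parameter
tolerance 10⁻⁸. The bottom asymptote is bounded below by 0 — a viability
fraction cannot be negative — which keeps the fit identified when the
tested range does not reach the lower plateau. Fits with hill ≤ 0 or
top ≤ bottom (monotone-increasing data) are flagged not converged.

IC_f uses the relative, asymptote-anchored definition
c = ic50·(f/(1−f))^{1/hill}, exact for the 4PL; IC₅₀ is returned exactly at
f = 0.5. The default simulated assay plants IC25 = 192 µM with Hill
slope 4 and nine linearly spaced concentrations over 0–300 µM in
triplicate with 5% additive noise: the source design fixes only the
range, the triplicates, and the IC25, and this slope/spacing keeps all
four parameters identifiable within the range (a two-fold dilution
series concentrates levels far below the IC50 and leaves the lower
plateau unobserved, roughly tripling the IC25 error).

## Problem sizes and determinism

The test suite and the acceptance script run screens of 2,000 genes × 2
guides (calibration and recovery), annotation universes of 20,000 genes
with 40 disease terms, 1,000-set resampling nulls (100,000 for the
tight SD check, on a 2,000-gene universe), and small 50-gene screens for
FASTQ round trips — sizes at which every Monte-Carlo bound in the tests
has comfortable slack. Every stochastic stage takes an explicit seed;
the pipeline derives and records per-stage sub-seeds in
`run_manifest.yaml`, and reruns are byte-identical.

## Limitations

The NB guide test reduces the exposed replicates to their rounded mean —
a single NB evaluation rather than a per-replicate likelihood — which is
a declared simplification relative to full count-model fits. Planted
effects are gene-homogeneous, so recovery rates here are upper bounds on
what heterogeneous real guides would give. The enrichment analysis
assumes the candidate set is exchangeable with random sets under the
null; annotation bias toward well-studied genes, present in real
gene–disease resources, is not simulated.
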