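# Methods

## Scope and data model

`anchorgda` operates on a genes × samples numeric expression matrix with a
one-group-per-sample annotation, gene signatures in GMT format, and
tab-separated drug-perturbation tables. Gene identifiers are uppercased
symbol strings; matching everywhere is exact string equality after
uppercasing. Expression units are taken as provided (log-intensity, RPKM,
z-scores); nothing in the package rescales on read. Missing expression
values are not supported — impute or filter upstream.

## Preprocessing

**Probe collapse.** When several probes map to one gene, the probe with the
highest sample variance (n−1 denominator) is kept; variance ties break to
the lexicographically smallest probe identifier so results are
deterministic. Unmapped probes are dropped and counted.

**Z-scoring.** Per-gene standardisation to mean 0, sample sd 1 within a
dataset. Constant rows are dropped with a log entry, never mapped to zeros.
The transform is idempotent up to floating tolerance. A cross-dataset
"combined" z (weighted mean difference over pooled standard deviation) is
*not* implemented: the per-gene within-dataset standardisation is the
operative reading, and meta-analytic pooling across platforms is out of
scope.

**Differential screen.** Per-gene ordinary (equal-variance) one-way ANOVA;
with two groups this is the pooled t-test (F = t²). Genes constant in every
group get p = 1. Benjamini–Hochberg adjustment runs across all genes
tested. Tukey HSD pairwise comparisons are exposed for ≥3 groups; the
two-group pipeline path reports the ANOVA p directly.

## The anchor screen

Within one sample group (≥3 samples), every gene's Pearson r to the anchor
is computed; p-values use the exact t transform t = r·√((n−2)/(1−r²)) with
n−2 df, two-sided. Genes with zero within-group variance are excluded and
counted. Default membership in the positively correlated list (GSPC)
requires r ≥ 0.50 **and** p < 0.05; the negatively correlated list (GSNC)
analogously at r ≤ −0.50. The dual criterion is deliberate: at n = 10,
|r| = 0.50 alone is far from significant (the p < 0.05 cut corresponds to
|r| ≥ 0.632), so "threshold-only" and "significance-only" readings genuinely
differ. Both knobs are explicit (`ScreenThresholds`), and the anchor itself
is always in GSPC (r = 1, p = 0).

## Signature deconvolution

For query size n, signature size D, universe N: expected overlap E = n·D/N,
representation factor RF = x/E, percent of signature 100·x/D, and the exact
hypergeometric point and upper-tail probabilities. Implementation details:

- Probabilities are delegated to `scipy.stats.hypergeom` (log-space
  internals); a brute-force rational enumeration (exact integer
  combinatorics) serves as an independent oracle in the tests for every
  (N ≤ 60, D, n, x), at relative error 1e−10.
- When the tail underflows double precision, −log₁₀ p is recovered from the
  log-survival function, so extreme enrichments keep a finite magnitude.
- The universe defaults to N = 20,203 (annotated RefSeq genes) and is a
  property of the signature collection, *not* recomputed from the matrix:
  this reproduces the standard fixed-universe arithmetic regardless of
  platform coverage. A strict mode intersects query and signatures with a
  supplied measured-gene set and uses its cardinality as N instead.
- Percent of signature is truncated (not rounded) to two decimals via
  integer arithmetic — e.g. 37/78 → 47.43 — matching the display convention
  of the enrichment reports this package interoperates with. RF and
  −log₁₀ p are rounded to two decimals in tabular output only; the
  underlying record keeps full precision.
- Significance across a collection is unadjusted by default (each signature
  tested on its own); BH adjustment across the collection is a flag. The
  `enriched` call requires RF > 1 and (adjusted) tail p < α.

## ROC

AUC is the Mann–Whitney statistic with midrank ties: the probability that a
random case outranks a random control on the marker. The 95% CI uses the
Hanley–McNeil standard error (DeLong would be the variance-exact
alternative; not implemented), clipped to [0, 1]. The p-value against
AUC = 0.5 is the tie-corrected normal approximation to U. Orientation is
never auto-flipped — an up-regulated marker gives AUC > 0.5 with cases as
the positive class — but a `flip` flag exists. The Youden-optimal threshold,
its accuracy and percent error are reported alongside.

## Drug-reversal ranking

The combined score C = z·log₁₀(p) is zero when z = 0 or p = 1 and strongly
negative for a significant opposing perturbation (z > 0, p ≪ 1); ranking
sorts ascending with name tie-breaks, after filtering at q < 0.05. For
offline construction of perturbation tables, `signature_similarity` scores
explicit up/down gene sets: with query q and perturbation t,

    raw = (|qU∩tD| + |qD∩tU| − |qU∩tU| − |qD∩tD|) / (|qU| + |qD|)
    similarity = −raw

so a perfect reverser scores −1 and a perfect mimic +1 (opposing = negative,
the convention of published reversal tables). Its p is the hypergeometric
upper tail of the reversal-overlap count; z carries the standard-normal
quantile magnitude of p, floored at 0 for p ≥ 0.5, with positive sign for
opposing perturbations — so significant reversers get z > 0 and C < 0. This
is a deliberately simple local set-overlap score for building and testing
ranked tables, not a reimplementation of any server's corpus-based
statistic.

## Synthetic data

The generator plants exactly the structure the pipeline is built to detect:

| parameter | default | meaning |
|---|---|---|
| n_neg / n_pos | 10 / 13 | control / case sample counts (the emulated study's group sizes) |
| n_genes | 2000 | measured genes, anchor included |
| anchor_shift δ | 1.1 sd | case-group mean shift of the anchor; theoretical AUC Φ(δ/√2) ≈ 0.78, the discrimination level the anchor marker is reported to achieve |
| block sizes | 300 / 400 | genes correlated / anti-correlated to the anchor |
| rho_pos / rho_neg | 0.8 / 0.8 | target Pearson r of block genes to the anchor within cases |
| signature specs | immune-like 120 (60% from + block); neural-like 900 (50% from − block, capped at the block size) | planted signature memberships |
| universe N | 20,203 | fixed annotation universe |

Correlated blocks are generated as g = ρ·ẑ_anchor + √(1−ρ²)·ε within the
case group only (the screen runs on cases; controls get independent noise
for non-anchor genes), so within-case correlation is planted and
between-group structure comes only from the anchor shift. One global seed
drives a named `SeedSequence` substream per component, so adding a stage
never perturbs earlier draws and equal seeds give bit-identical output.
When a signature spec requests more background genes than a small
simulation has, the draw is capped at availability with a logged warning.

What the generator does **not** emulate: probe-level noise, platform
effects, heteroscedasticity, library-size or composition effects of
RNA-seq counts, correlated background structure. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability of
planted signal under the Gaussian model — not robustness to real microarray
or RNA-seq artefacts.

## Problem sizes and numerical choices

The test suite runs the null calibration at 5000 genes × 10 samples, the
end-to-end recovery at the default 2000-gene configuration, the AUC
convergence checks at 200–500 samples per group, and the exhaustive
hypergeometric oracle at N ≤ 60 — sizes chosen so each property is measured
well inside Monte-Carlo error while the whole suite stays interactive.
Stochastic assertions use fixed seeds and tolerances stated per test (the
binormal-AUC convergence check asserts the mean over its three replicates,
since its per-replicate Monte-Carlo sd is ~0.014 against a 0.02 band).
Degenerate inputs are errors, not silent defaults: empty queries, empty
collections, constant anchors, groups below minimum size, p outside (0, 1].

## Known limitations

- The screen treats genes independently; no correction for the multiplicity
  of the genome-wide correlation scan is applied to list membership (the
  α is per-gene, matching standard practice for this workflow).
- The fixed-N universe ignores platform coverage unless strict mode is used;
  RF and p are then conventional rather than strictly model-consistent.
- Hanley–McNeil CIs are approximate and can be wide/clipped at small n.
- Ordinary ANOVA assumes equal group variances; no Welch option.
- The drug-ranking module scores user-supplied or synthetic perturbation
  tables; it does not ship any perturbation corpus.
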