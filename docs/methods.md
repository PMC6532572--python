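# Methods

## Synthetic count model

Counts are negative binomial in the mean/dispersion parameterization of
the RNA-seq DE literature: for gene g in sample s,

    mu(g, s) = sf(s) * base_mean(g) * induction(genotype(s), g)^[condition(s) = -Fe]
    var      = mu + alpha * mu^2

with `alpha = 0` degenerating to Poisson (drawn from `numpy`'s Poisson
in that case, NB(r = 1/alpha, p = r/(r + mu)) otherwise). Each gene's
stream is seeded by the pair (scenario seed, gene index), so extending
a scenario with more genes never changes the counts of existing genes;
the scenario-level stream (base means, optional size factors) is keyed
separately.

The default scenario mirrors the study design: 2 genotypes (wildtype,
clf) x 2 iron conditions (+Fe, ferrozine-imposed -Fe) x 3 biological
replicates. FIT-set genes cycle through the three published induction
pairs (wt 3.9 / clf 5.0, 13.7 / 40.8, 11.3 / 22.4 — *FIT*, *FRO2*,
*IRT1*), PYE-set genes through (4.9 / 4.6, 5.9 / 5.7, 17.5 / 16.4 —
*PYE*, *BTS*, *FRO3*), background genes are unregulated. Defaults the
study does not pin down and their rationale:

- **dispersion alpha = 0.05** per gene — a typical biological-replicate
  dispersion for bulk RNA-seq of a well-powered tissue; configurable
  per gene.
- **base means log-uniform on [50, 500]** — moderately expressed genes,
  so fold-change estimates are count-limited rather than
  pseudocount-limited.
- **gene length 1,000 bp** unless specified (FPKM checks need a known
  length), **size factors 1** with an optional log-normal (sd 0.1)
  library-size perturbation to exercise normalization.

The generator emulates design, effect sizes and NB noise; it does not
emulate read-level artifacts, batch effects, gene-gene correlation or
length-dependent counting biases, so passing tests speak to the
statistical procedure, not to alignment/quantification issues in real
data.

## Quantification

Size factors are median-of-ratios (genes with a zero anywhere are
excluded from the median), rescaled to geometric mean 1. FPKM is
`count * 1e9 / (length_bp * raw library total)`. Per-genotype fold
change is the ratio of arithmetic mean normalized counts (-Fe over
+Fe) with pseudocount 0.5 added to both means — finite on all-zero
genes (fc = 1 exactly), negligible for large counts; `lfc = log2 fc`
and `delta = lfc_clf - lfc_wt` are stored exactly as those
expressions. Fold changes use normalized counts, not FPKM (an
FPKM-based option exists behind a flag), because the decision variable
is a within-gene ratio where length cancels.

## Asymmetry test

Observed statistic: proportion of focal-set genes with delta strictly
positive; a tie (delta = 0) counts as not-above, reading "more induced"
as a strict inequality. Null: focal/comparator labels are exchangeable
within the pooled set; each permutation draws |focal| labels without
replacement and recomputes the proportion. p-values use the add-one
rule, so the smallest attainable value is 1/(n_perm + 1); n_perm
defaults to 10,000, enough to resolve p < 0.001. The default
alternative is one-sided (focal more induced in clf), matching the
directional hypothesis; two-sided doubles the smaller tail, capped
at 1. Because only the signs of the deltas and the set labels enter,
the p-value is invariant to strictly monotone, sign-preserving
transforms of the deltas.

The Mann-Whitney companion compares the two sets' delta distributions:
U is the pair count with midrank ties; the p-value is exact (full U
distribution) when n1*n2 <= 400 with no ties, otherwise the normal
approximation with tie-corrected variance and continuity correction.

### Calibration

Under an exchangeable null the permutation p-value is valid
(P(p <= a) <= a) but discrete: with 45-gene sets the proportion has
only 46 attainable values and the test rejects at ~3% for nominal 5% —
conservative, the safe direction. The calibration suite therefore
measures the rejection rate at 250-gene sets (2,000 trials, 999
permutations each), where the support is fine enough for the rate to
reach the nominal level, and separately asserts that the 45/45
configuration never exceeds it.

## Differential-induction caller

A deliberately simple stand-in for shrinkage-based NB DE tools, so
synthetic pipelines can run end to end: per gene and genotype,
method-of-moments dispersion `(s^2 - m)/m^2` averaged over the two
conditions, floored at 1e-8; variance of each condition mean floored at
the Poisson bound; Wald statistic lfc/SE with a delta-method SE on the
log2 scale (pseudocount 0.5 in the means) and two-sided normal p;
BH across genes; "up-regulated" applied as a sign post-filter at
padj < 0.05. No dispersion sharing across genes, no outlier or
independent filtering — at n = 3 replicates the type-I error on Poisson
data sits in the documented [0.03, 0.08] band rather than exactly 0.05.

## qPCR and ChIP-qPCR

Relative expression: per sample, dCt = mean Ct(target) − mean
Ct(reference gene); expression 2^(−dCt); reported as the ratio to a
calibrator sample (which makes the result equal to the usual ddCt
quantity). Amplification efficiency is fixed at 2 per cycle; technical
replicates are averaged arithmetically before dCt. Plate-wide Ct
offsets cancel inside dCt.

Percent input: adjusted input Ct = ct_input − log2(1/input_fraction)
(fraction 0.10 by default, i.e. −log2(10) ≈ −3.32 cycles); percent =
100 · 2^(adjusted − ct_ip). Relative enrichment divides by a calibrator
sample per region; IgG subtraction (floored at 0, logged) and H3
normalization are available but off by default since the reference
normalization is input-only.

## Clustering and over-representation

Replicates are averaged within each genotype x condition cell before
per-gene z-scoring (n−1 denominator; constant rows are dropped with a
logged notice). Genes are agglomerated with Euclidean distance and
average linkage — the study names neither, so both are configurable —
via scipy; merge order on exactly tied distances follows scipy's
deterministic input-order behaviour rather than an explicit
smallest-index rule (ties have measure zero for continuous z-scores).
Over-representation of a term in a cluster is the hypergeometric upper
tail P(X >= k) with BH across terms.

## Problem sizes

The shipped experiments use 240 genes x 12 samples for the headline
scenario, 100 replicates per condition x 10 seeds for single-gene
fold-change recovery (with 100 unregulated anchor genes so
median-of-ratios normalization is estimable — with a single gene the
estimator would absorb the signal entirely), 2,000 trials for
calibration, and exhaustive enumeration oracles for pools <= 12 genes
and universes <= 25. These sizes make every claim testable in seconds
to a couple of minutes on one CPU while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The NB Wald caller is a calibrated stand-in, not a replacement for
  shrinkage estimators; at n = 3 its dispersion estimates are noisy.
- The randomization scheme (label permutation within the pooled sets)
  is the minimal null consistent with a two-set comparison; other
  schemes (e.g. rotating gene labels genome-wide) would answer
  different questions.
- Fold-change estimates at n = 3 are biased slightly toward 1 by the
  pseudocount for weakly expressed genes; the recovery experiments
  quantify the estimator at n = 100.
- The qPCR calculators assume 100% amplification efficiency and a
  single reference gene.
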