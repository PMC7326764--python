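# Methods

This note documents the statistical models behind each `strokenet` stage,
the parameters that matter, the numerical conventions, and what the
synthetic generators do and do not emulate.

## Cohort representation and genotype codings

Genotypes are minor-allele dosages (0/1/2, NaN missing) in a subjects × SNPs
matrix; the minor allele is defined per dataset by observed frequency, with
a 50/50 tie broken toward the lexicographically smaller allele string, so
the orientation is reproducible from the data alone. Codings follow the
conventional genotype groupings: *dominant* contrasts minor-allele carriers
(dosage ≥ 1) with non-carriers, *recessive* contrasts minor homozygotes with
the rest, *genotypic* keeps three levels, *additive* keeps the dosage.
Missing dosages propagate and are removed pairwise per analysis — no
imputation, which is conservative for a small candidate panel.

## Hardy-Weinberg QC

For genotype counts (n_AA, n_Aa, n_aa) the allele frequency is estimated as
q̂ = (2·n_aa + n_Aa)/2N and Pearson's χ² compares observed counts with
(p̂², 2p̂q̂, q̂²)·N on 1 df (three classes, one estimated parameter).
Monomorphic SNPs return χ² = 0, p = 1 with a flag rather than an error so
scans over a panel never abort. Under exact HWE sampling the p-values are
uniform; the test suite checks this by KS test over 1000 simulated SNPs.

## Association scans

"Correlation" between a coded SNP and a factor is test-by-type:

| coding levels | factor | test |
|---|---|---|
| 2 (dominant/recessive) | continuous | point-biserial correlation (t-test) |
| 3 (genotypic) | continuous | one-way ANOVA F |
| any | binary (smoking, drinking, subtype) | Pearson χ² on the contingency table |

Both continuous-factor tests reduce to the p-value of a linear regression on
the coding, so the choice introduces no covert covariate adjustment. The
2×2 χ² is uncorrected by default (matching common genetics-software
defaults), with a Yates flag. Scans report raw p-values; Benjamini-Hochberg
is available as a post-processor but off by default, since the analysis
tradition here reports unadjusted per-test significance.

## Causal mediation (ACME/ADE/total/proportion mediated)

Under sequential ignorability, two component models are fitted separately
with statsmodels GLM: a Gaussian identity-link mediator model M ~ T (+X)
and a binomial-logit outcome model Y ~ T + M (+X) (Gaussian for continuous
outcomes). Covariates default to none; age/sex adjustment is a flag.
Inference is quasi-Bayesian: `nsim` (default 1000, floor 100) parameter
vectors are drawn from each model's asymptotic normal; per draw, potential
mediators under control/treatment are simulated including the mediator's
residual noise (one shared noise draw per subject per parameter draw, which
leaves all marginal quantities unchanged while reducing Monte-Carlo
variance), and the four potential-outcome means are evaluated analytically
through the inverse link. Effects are risk differences averaged over
subjects and over the two treatment arms, so that total = ACME + ADE holds
per draw to machine precision. Treatment contrast is 0 vs 1 for binary
codings (0 vs 2 additive). Percentile 95% intervals; two-sided Monte-Carlo
p = 2·min(P(draw ≤ 0), P(draw ≥ 0)) floored at 1/(nsim+1). Proportion
mediated is the draw-wise ratio ACME/total, summarized by the median with
draws clipped to [−1, 2] (flagged when clipping occurs) and flagged unstable
when |total| is numerically zero in more than 10% of draws.

Two calibration facts shape the tests: in the all-linear limit ACME
converges to the product of path coefficients a·b; and the test attains its
nominal level at the *boundary* null (a ≠ 0, b = 0) while being
conservative at the complete null (a = b = 0), where rejecting requires
both paths to look significant at once (rejection ≈ α²). Type-I error is
therefore asserted at the boundary null, the least favorable point of the
composite null.

Perfect separation in the logistic fit is detected from fitted
probabilities (all cases ≈ 1 and controls ≈ 0), not coefficient magnitude,
so legitimately large intercepts from non-centered clinical mediators do
not false-alarm. Rank-deficient designs name the collinear column.

## MDR

For a k-SNP subset (k ≤ 4; exhaustive search over C(14, k) is trivial),
each of the 3^k multilocus cells is labeled **high-risk** iff its
case:control ratio ≥ T = N_case/N_control, evaluated as
cases·N_control ≥ controls·N_case to avoid division: ties go high, and a
cell with cases but no controls is high. Empty cells are labeled empty and
predicted low-risk when encountered at test time. The labeling is scored
by balanced accuracy (mean of sensitivity and specificity; with ~1:1
case:control it nearly equals plain accuracy but stays robust in subtype
subsets), which is provably ≥ 0.5 on training data under this rule.
Evaluation is stratified 10-fold CV on one shared fold assignment per
subset size; the best model per size maximizes mean testing balanced
accuracy, and CVC counts the folds in which that subset also had the best
within-fold training accuracy. Significance uses the substitution test:
case labels are permuted, the full search statistic recomputed, and
p = (1 + #perm ≥ observed)/(n_perm + 1); n_perm ≥ 19 is enforced so α = 0.05
is resolvable. Pooled 2×2 (high/low × case/control) odds ratios use the
Woolf interval exp(ln OR ± 1.96·√Σ1/cell), with Haldane-Anscombe +0.5
correction applied (and flagged) only when a zero cell occurs; all-one-label
tables are flagged degenerate instead of reporting an OR.

Entropy decomposition: with H(C) the class entropy in bits, each SNP's main
effect is I(A;C) = H(C) − H(C|A) and each pair's interaction gain is
I(A,B;C) − I(A;C) − I(B;C) — positive for synergy, negative for redundancy —
reported in bits and as % of H(C). The interaction dendrogram applies
average-linkage clustering to d = 1/(synergy − min synergy + ε), so the most
synergistic pairs merge first; it is exported as Newick.

## Competing-mRNA network

Target maps are deduplicated miRNA→gene pairs, optionally filtered at a
maximum binding free energy of −20 kcal/mol (weaker-binding predictions
dropped; files without an energy column pass through with a log note).
The shared-miRNA statistic is the upper-tail hypergeometric probability
P(X ≥ r) with population m (miRNAs in the filtered map), t and n targets
per gene, r shared — computed from log-gamma binomial coefficients and a
log-sum-exp over the tail, stable for m in the hundreds; r = 0 gives
exactly 1. Only pairs sharing ≥ 1 miRNA are tested (others have p = 1 by
construction), and when hub ("seed") genes are given only seed-incident
pairs are tested, yielding a hub-centric network without an all-pairs
explosion. Edges require p < α (default 0.05, raw; BH by flag).

Topology: degree; betweenness normalized by (N−1)(N−2)/2; closeness within
components with the Wasserman-Faust reachability scaling (isolated nodes:
0, flagged by convention). The three top-5 rank lists and their
intersection reproduce the "hub by every index" logic. The scale-free
check is a least-squares line on log10 frequency vs log10 degree over
nonzero-frequency degrees (≥ 3 distinct degrees required).
Over-representation analysis is the same hypergeometric upper tail on
(N universe, K term, n query, k hits), with gene sets taken as provided in
the GMT — GO DAG propagation is out of scope; membership is an input.

## Synthetic data

Generators are pure functions of spec + seed; one master seed is expanded
via `SeedSequence(entropy, spawn_key)` per sub-generator. Defaults encode
the study conditions: 507 cases / 503 controls, a 14-SNP panel with MAFs
0.22–0.45, risk factors at plausible adult clinical baselines (e.g.
systolic BP 135 ± 18 mmHg, HDL 1.3 ± 0.3 mmol/L), baseline outcome
log-odds −0.6, TOAST subtypes assigned 0.45/0.35/0.20. A planted pathway
adds a mediator units per coded-genotype unit and contributes
b·(M − baseline) + c′·T to the outcome logit (b is per mediator unit of
deviation, keeping the intercept interpretable). Cohorts are collected by
rejection sampling to hit exact case/control counts, matching the
retrospective design that the odds-ratio analyses assume. Epistasis data
draw case status prospectively from a k-locus penetrance table; the XOR
checkerboard helper (high where the dosage sum is odd) has exactly flat
marginal penetrance at MAF 0.5, i.e. pure epistasis. Target maps give each
gene a uniform random target count in [3, 15] of m = 100 miRNAs, with
planted modules sharing dedicated miRNA cores.

Deliberately not emulated: linkage disequilibrium and haplotype structure,
realistic covariance of the lipid panel, genotyping error, and
sequence-level miRNA binding. Passing tests therefore demonstrate
correctness and calibration of the *methods* under their own assumptions,
not robustness to those real-data features.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use sizes chosen to make
Monte-Carlo assertions sharp while keeping a laptop run short: 1000
simulated SNPs for HWE uniformity; n = 4000 and nsim = 1000 for the
linear-limit ACME (tolerance ±0.05 ≈ a few Monte-Carlo SDs); 500 replicates
at nsim = 100 for type-I error (binomial SD ≈ 0.010 around 0.05, asserted
band [0.02, 0.08]); 20 seeds × n = 1600 for XOR recovery at penetrance
0.3/0.7; 200 random instances for MDR brute-force equivalence; 2000 null
pairs for edge-test super-uniformity (bound 0.07); 50 random graphs ≤ 30
nodes for centrality oracles. Equalities against enumeration oracles are
asserted to 1e-12 and the per-draw effect decomposition to 1e-10.

## Known limitations

- No sensitivity analysis for the sequential-ignorability assumption; the
  mediation results are model-based and unadjusted by default.
- MDR cross-validated accuracies depend on fold randomness; only pooled
  full-data odds ratios are fold-free.
- The competing-pair test conditions on per-gene target counts; it does not
  model correlated miRNA families (which would inflate sharing).
- The pipeline assumes complete-case analysis per stage; heavy genotype
  missingness will shrink the effective n differently across stages.
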