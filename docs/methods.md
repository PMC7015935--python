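# Methods

## Scientific setting

Bulk RNA-seq of tumors under PD-1 blockade shows two coordinated
transcriptional features of durable response: up-regulation of
cancer-associated-fibroblast (CAF) marker genes — stroma remodeling — and
down-regulation of cell-division programs (the G2M-checkpoint and
E2F-targets pathways). `icisig` turns those observations into a tested,
reusable pipeline: derive a stroma signature and a proliferation signature
from a labeled discovery cohort, score any cohort on them, and classify
response from the two scores jointly. All stages run on synthetic cohorts
generated by the package itself, so the statistical behavior of every step
is testable without any sequencing data.

## Expression preprocessing

**Expression filter.** Genes without at least 1 read in at least 3 samples
are removed before differential expression. The filter is idempotent and
acts on genes only; the sample set is never changed.

**FPKM.** `FPKM[g,s] = counts[g,s] * 1e9 / (library_size[s] * length_bp[g])`,
with the library size taken as the raw column sum of the matrix being
converted. Filtering is applied before FPKM, so library sizes refer to the
filtered-in matrix; this choice is a convention of this package and is
documented here because either order is defensible.

**Mean normalization.** Before scoring, each gene is divided by its mean
over the cohort being scored: `norm[g,s] = (x[g,s] + eps) / mean_c(x[g,.] + eps)`
with `eps = 0.01` FPKM. The pseudocount exists solely so the geometric mean
is defined at zero expression; 0.01 FPKM is well below meaningful
expression. By construction each gene's cohort mean of normalized values is
exactly 1, and scores are invariant to rescaling any gene's row (gene
length, probe efficiency, etc. divide out). Normalization is per cohort:
the samples scored together define the reference mean, and paired
pre/on-treatment samples scored jointly are normalized jointly.

## Differential expression

The DE stage is a deliberately simple, fully documented negative-binomial
(NB) Wald test, not a port of a shrinkage-based engine (no shrunken
dispersions, no outlier or independent filtering, no covariates). Its role
in this pipeline is to rank genes for signature selection, and its observed
calibration (below) is adequate for that purpose.

- **Size factors**: median-of-ratios. Reference genes are rows positive in
  every sample; each sample's factor is the median ratio of its counts to
  the per-gene geometric mean. Factors are rescaled to geometric mean 1, so
  they are identifiable and permutation-stable.
- **Dispersion**: per-gene method of moments on size-factor-normalized
  counts, `alpha = (pooled within-group variance - mean) / mean^2`, floored
  at `1e-8`; sub-Poisson moment estimates are treated as Poisson.
- **Fold change**: `log2fc = log2((m_R + c) / (m_N + c))` with pseudocount
  `c = 0.5` normalized counts, keeping fold changes finite for zero-mean
  groups. Positive log2fc means higher in responders.
- **Test**: Wald contrast of log group means, with the delta-method
  standard error `sqrt(v_R/(m_R+c)^2 + v_N/(m_N+c)^2)` where
  `v_g = (m_g + alpha m_g^2)/n_g`. The statistic is referred to a
  two-sided t distribution with `n_R + n_N - 2` degrees of freedom rather
  than the normal — a small-sample correction reflecting that the variance
  is itself estimated from few samples. Measured on null simulations
  (8 vs 8, dispersion 0.1, 2,000 genes, ten seeds) the rejection rate at
  p < 0.05 is 0.049 and the Kolmogorov–Smirnov distance of the p-values
  from uniform is 0.023. Genes at zero in both groups get p = 1,
  log2fc = 0, and an `all_zero` flag.
- **Multiple testing**: Benjamini–Hochberg step-up,
  `q_(i) = min_{j>=i} m p_(j)/j` capped at 1. Implemented directly (it is
  part of the stage's contract) and cross-checked against
  `statsmodels.multipletests` in the test suite.
- **DEG selection**: `q < 0.05` and `|log2fc| > 1` — FDR below 5% with fold
  change strictly above 2.

## Signatures and scores

- **Stroma signature**: among the CAF markers, candidates with `log2fc > 0`
  and unadjusted `p < 0.05`, ranked by p ascending with ties broken by
  |log2fc| descending then gene id; the top 10 are taken. Note the
  *unadjusted* p here, in contrast to the FDR threshold for global DEG
  lists: the candidate universe is a small curated marker panel, not the
  whole transcriptome. Fewer than 10 candidates yields a shorter signature
  with a warning.
- **Proliferation signature**: unique genes of the merged G2M-checkpoint
  and E2F-targets sets with `log2fc <= -1` (threshold inclusive; this
  differs deliberately from the strict `> 1` used for DEG selection — the
  two rules are kept distinct exactly as specified for each).
- **Scores**: per sample, the geometric mean
  `exp(mean_g ln norm[g,s])` over the signature genes. Strictly positive,
  centered near 1.
- **Combination score**: `ln(stroma) - ln(proliferation)`. Responders sit
  high on stroma and low on proliferation, so the log-ratio is monotone in
  both; it reduces the 2-D score plane to one axis whose half-planes of
  slope 1 it reproduces exactly. The published analysis never formalizes
  the combination rule, so this log-ratio is this package's explicit
  stand-in; an alternative independent-thresholds rule (responder iff
  stroma >= t1 and proliferation <= t2) is available via
  `combination_classify(method="two_threshold")`.
- **Threshold**: predicted responder iff combination score >= threshold.
  When fitted, the threshold maximizes Youden's J over candidate cuts at
  the midpoints between adjacent distinct scores plus the extremes (the
  standard ROC convention; a separable training set gets the center of its
  margin, which transfers better to new cohorts than a cut placed on an
  observed score), ties resolved to the smaller threshold.

## Evaluation utilities

Sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp), printed to one
decimal with half rounded away from zero; an empty positive class yields an
*undefined* (None) sensitivity, never 0. Response-rate summaries count
durable (DR) plus short-lived (SR) responses as responding. Group
comparisons use the two-tailed Mann–Whitney U test (exact enumeration for
tie-free samples with n1+n2 <= 12, otherwise normal approximation with tie
correction) and the two-tailed Wilcoxon signed-rank test for paired
pre/on-treatment samples (zero differences dropped; all-zero input returns
p = 1 with a warning). Both wrap `scipy.stats`. Survival uses the
Kaplan–Meier product-limit estimator via `lifelines`, with the median
defined as the smallest time with S(t) <= 0.5 (inclusive — so censoring
after the last event never moves the median), and the two-group log-rank
test.

## Synthetic cohorts

**Expression.** Counts are drawn per gene and sample as
`NB(mean = q_g · sf_s · 2^(effect_g · [s in DR]), dispersion alpha)`.
Defaults emulate the discovery-cohort conditions: 6 DR vs 8 NR samples,
2,000 genes, 50 CAF markers with 10 planted at log2 effect +1.5, 120
cell-cycle genes (split into overlapping G2M/E2F stand-in sets) with 7
planted at −1.5, dispersion 0.2, log-normal base means (meanlog 4,
sdlog 1.5) and library sizes (sdlog 0.25) — a typical bulk RNA-seq shape.
Gene lengths are uniform on 500–10,000 bp. The paired mode adds a
pre-treatment sample per subject without the planted effect and a shared
within-pair log-mean random effect (sd 0.1) so paired tests are exercised.
Randomness flows from one seed through spawned child streams; the cohort
*structure* (marker assignment, planted genes, base means, lengths) is
keyed by `config.seed` while the count *sampling* stream can be redirected
with `counts_seed` to draw independent cohorts sharing the same underlying
biology — that is what "held-out validation cohort" means here.

**What the generator does not emulate**: mapping or quantification noise,
batch effects, varying tumor purity or immune composition, correlated gene
modules beyond the planted ones, or mutational processes. Passing the
recovery and held-out tests therefore demonstrates that the pipeline's
selection rules and scores behave correctly under the assumed NB model at
the stated effect sizes — not that real cohorts of this size would show the
same performance.

**Tumor growth and survival.** Volumes follow
`V = L × W × D × π/6` from caliper dimensions. Trajectories are piecewise
exponential from a ~100 mm³ baseline: non-responders grow at 0.08/day;
responders switch to −0.10/day at day 6; short-lived responders additionally
relapse at +0.09/day from a random day in 20–45; multiplicative log-normal
measurement noise (sd 0.03) is applied. Response categories are assigned
from the realized trajectory by explicit rules that operationalize the
qualitative categories for testing only: DR — volume never exceeds 1.2×
baseline after day 14 and ends at or below baseline; SR — shrinks >= 30%
below baseline then exceeds baseline before study end; NR — otherwise.
(The rates are chosen so the intended trajectory families actually satisfy
these rules, e.g. responders must clear the 1.2× bound by day 15 despite
pre-onset growth.) Animals reach the survival endpoint on the first
measurement day the volume is >= 1500 mm³, else are censored at study end
(day 90). The treated-arm category mixture follows the observed tumor
counts (13 DR, 6 SR, 34 NR of 53).

## Problem sizes and run times

The recovery experiment uses 25 discovery cohorts, the held-out experiment
20 train/test cohort pairs, and the null calibration 10 cohorts of 2,000
genes; the whole acceptance script completes in a few seconds on one CPU,
and the test suite in well under a minute. These sizes give stable
averages (recovery pass fraction and held-out performance move by a few
percent across base seeds).

## Known limitations

- The NB Wald test is not a replacement for a mature DE engine on real
  data; it has no dispersion shrinkage and will be noisy for weakly
  expressed genes. It exists to rank genes for signature derivation.
- Published signature gene identities live in figure panels and
  supplementary material and are deliberately not hard-coded; signatures
  are always derived from data or supplied by the user as GMT.
- Orthology mapping between species is the caller's responsibility; gene
  identifiers are matched case-sensitively after whitespace stripping.
- Affinity prediction for neo-antigen candidates is an external input; the
  package only enumerates peptides and filters supplied IC50 tables at the
  strict < 500 nM cutoff.
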