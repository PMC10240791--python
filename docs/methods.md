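# Methods

This note documents the models, numerical choices and known limitations of
the `timedrivers` pipeline, in the order the stages run.

## Damaging alteration calling

Mutation consequence classes (truncating, damaging missense, damaging
splicing, hotspot, benign/other) are inputs: upstream variant annotation is
trusted, not recomputed. Copy-number input is gene-level total copy number
with the fraction of the transcript covered by the underlying segment; a
helper intersects standard SEG segments (1-based inclusive on disk,
converted to 0-based half-open internally) with BED gene models and applies
the ≥ 25% transcript-coverage rule.

Calling rules, with the sample's purity ρ and ploidy ψ:

* homozygous loss: copy number 0 and FPKM/ρ < 1;
* heterozygous loss: copy number 0 or 1 and FPKM/ρ > 1 — on its own this is
  a single hit and produces no event; combined with any damaging mutation
  in the same sample-gene it becomes one loss-of-function "double hit";
* damaging gain: copy number > 2ψ (strict), kept only if the gene's
  expression in gain samples is above the same-cancer-type baseline
  (one-sided Wilcoxon rank-sum; Benjamini–Hochberg within cancer type
  across candidate-gain genes; FDR < 0.05). The baseline is the same-type
  samples without a candidate gain in that gene; genes gained in every
  sample of a type are untestable and dropped with a warning.

Role consistency keeps LoF on tumour suppressors, GoF on oncogenes, both on
unclassified drivers. The recurrence filter retains a driver when its
damaged-sample count is ≥ 5 **or** its damaged fraction is ≥ 2% (OR
semantics; both thresholds configurable). Retention is evaluated per cancer
type, so a driver can enter the design matrix in one type and not another.

## TIME features and discretization

Five features with per-feature default scoring:

| feature | default method | notes |
|---|---|---|
| IS  | single-sample enrichment (α = 0.25) | rank-based immune infiltration |
| CYS | k-means, k = 6, clusters folded 2-per-level | cytotoxicity |
| ICR | k-means, k = 3, identity mapping | T-helper/rejection axis |
| TIS | mean log2(FPKM+1) | see below |
| CPI | mean log2(FPKM+1) | pro-tumour inflammation |

TIS is scored as the unweighted mean of log2(FPKM+1) over its gene list:
the original housekeeping-normalized weighted score is not reproducible
from public descriptions, and a weight column in the signature file
substitutes weights when they are available. The single-sample enrichment
statistic ranks genes per sample (average ranks on ties), weights each gene
by |rank − (n+1)/2|^α, and sums the running deviation between the weighted
in-set and uniform out-of-set cumulative distributions while walking genes
from highest to lowest expression. Centering the rank weight makes the
statistic exactly odd under reversal of the expression ordering and
invariant under monotone transforms; it is a deliberate, documented variant
of the family of single-sample enrichment scores, not a re-implementation
of any one published tool.

Continuous scores are discretized per cancer type: score ≤ Q1 → low,
score ≥ Q3 → high, else medium (linear-interpolation quantiles). Boundary
ties fall to the extreme groups; in the fully tied degenerate case the
≤ Q1 rule wins and the group is all-low. Groups under 4 samples are set to
medium with a warning. Cluster-scored features carry their own level
mapping: clusters are ordered by mean signature z-score and folded per the
feature's map. K-means runs with 25 restarts on rows sorted by sample id,
making assignments independent of input order; the seed is fanned out from
the pipeline's global seed.

## Penalized continuation-ratio screening

The backward continuation-ratio factorization turns an ordered outcome
y ∈ {1..J} into J−1 conditional Bernoulli problems: cutpoint j (from J down
to 2) receives every sample with y ≤ j, with event y = j. Slopes are shared
across cutpoints; each cutpoint has its own unpenalized intercept. The
expanded rows form one logistic design, and the objective

    (1/N_exp) · Σ −log-lik  +  λ · Σ|β|

is minimized by cyclic coordinate descent inside an IRLS loop (probability
clamp 1e-5, convergence when the largest coefficient change is < 1e-7,
hard iteration cap raising an error on non-convergence). The path has 100
geometrically spaced λ values from λ_max — computed from the score at the
intercept-only fit, so all slopes are exactly zero there — down to
λ_max/100. Covariates are binary alteration indicators and are deliberately
not standardized. AIC = 2·df − 2·ℓ with ℓ the exact ordinal log-likelihood
(the expanded-data likelihood factorizes to it) and df counting every
non-zero coefficient, cutpoint intercepts included; ties select the larger
λ (sparser model). Path length, min-ratio, formulation (backward/forward)
and the df convention are package choices, documented here because the
upstream conventions they mirror vary between implementations.

Screening runs one fit per (cancer type, TIME feature, driver tier),
restricted to samples with ≥ 1 damaged driver of that tier and a defined
level; drivers altered in no retained sample are dropped from the design;
strata with a single observed level are skipped and logged. Non-zero β in
the AIC-selected model become records with a direction (β > 0:
medium/high; β < 0: medium/low) and an orientation: anti-tumour for
CYS/TIS/ICR with β > 0 or CPI with β < 0, pro-tumour for the mirror,
infiltration-only for IS (overall infiltration has no anti/pro sign and is
excluded from the anti-tumour burden).

**Selection calibration.** With a single strong planted effect the selected
β carries the planted sign in ≥ 95% of non-null selections (measured:
98–100%). Minimum-AIC selection is, however, known to be liberal: a pure
noise driver enters the selected model with probability ≈ 0.12–0.15, so the
probability that a no-effect stratum selects the exact null model decays
like 0.85–0.88 per candidate driver (measured 0.74–0.78 with two canonical
drivers at n = 200). Users should treat single weak records as screening
candidates, not confirmed interactions; the per-stratum fit log carries the
selected λ and df for auditing.

## Cancer cell fraction and clonality

For alt/depth reads at purity ρ, tumour copy number CNt, normal copy number
CNn and multiplicity m, the expected VAF at cancer cell fraction c is
ρcm / (ρ·CNt + (1−ρ)·CNn). The posterior over the grid 0.01..1.00 (step
0.01) is the normalized binomial likelihood under a uniform prior — a
deliberate, simple likelihood model; beta-binomial overdispersion is not
modelled. Multiplicity defaults to the observed-VAF point estimate clamped
to [1, CNt]. The point estimate is the grid argmax.

The 95% interval is the **highest-density region** — the smallest set of
grid points holding 95% of the mass, contiguous because the binomial
likelihood is log-concave along the grid — and a mutation is clonal when
the region reaches CCF 1. An equal-tail interval was considered and
rejected: it calls clonality only when the single top grid point carries
more than 2.5% of mass, and because a boundary posterior (true CCF 1)
spreads its upper tail over ~15–25 grid points, it misses ~19% of
genuinely clonal mutations at depths 80–140, whereas the highest-density
rule recovers ≥ 93% while keeping subclonal (CCF 0.3) specificity at 100%.
A driver is clonal in a sample when at least one of its damaging mutations
is; CNA-only drivers are not assessed at the mutation level. Copy-number
clonality from allele-specific segmentation is out of scope; externally
computed CNA CCF posteriors can be fed through the same interval rule.

## Burdens and response prediction

TMB is the raw per-sample somatic mutation count over all consequence
classes (a per-Mb divisor is available but unitless counts are the
default since cohort-internal comparisons only need ranks and medians),
summarized as the per-type median. The anti-tumour TIME driver burden
(anti-TDB) of a cancer type counts unique genes with ≥ 1 anti-tumour
record there; anti-TTB/anti-TOB restrict to tumour suppressors/oncogenes
(unclassified roles count in neither sub-burden). Burden–TMB association
is Pearson's r with configurable type exclusions.

Approval of immune checkpoint blockade is a *type-level* label: the model
deliberately does not claim patient-level response prediction. The
logistic model places independent Student-t (df 1, scale 2.5) priors on
standardized coefficients — the standard weakly informative default for
sparse logistic problems — with a flat prior on the intercept, and is fit
to the posterior mode by damped Newton (penalized IRLS with backtracking).
A variable budget of at most 3 predictors and at least 10 observations per
predictor is enforced as a precondition at small n. Reported coefficient
p-values are posterior-mode Wald statistics and are approximate.
Evaluation uses repeated stratified 5-fold cross-validation (default 100
repeats), pooling out-of-fold scores per repeat into a rank-statistic AUC.
At n = 32 a single null predictor's intrinsic AUC fluctuates by ~0.1, so
chance-level behaviour is assessed over an ensemble of null draws.

## Subtype analysis

Per-locus CNA states (0 neutral, 1 low, 2 high) are either supplied or
derived from gene copy number as |cn − round(ψ)| mapped to 0/1/≥2 — an
explicit stand-in for externally derived recurrent-CNA loci. Samples are
clustered by average-linkage hierarchical clustering on Euclidean row
distances (Ward is available); at k = 2 the cluster with the larger mean
total state is CNA-high. The normalized sample proportion of subtype i in
level j is (n_ij/n_i)/(N_j/N), satisfying Σ_i (n_i/N)·r_ij = 1
(property-tested). Ordered level distributions are compared by the
linear-by-linear (Mantel–Haenszel trend) chi-square, (N−1)·r² with integer
scores 1..J by default; per-driver frequencies by two-sided Fisher with BH
correction; per-sample burdens by tie-corrected Kruskal–Wallis.

## Synthetic cohorts

The generator emulates the structure of a multi-cancer-type tumour cohort:
per-type sample counts, purity ~ U(0.3, 0.95), ploidy ∈ {2, 3, 4} with
weights 0.6/0.25/0.15, drivers altered independently at a base frequency of
0.15 (typical of recurrently damaged drivers), role-consistent damaging
mutations, binomial read counts at depth ~ Poisson(100) under the CCF model
above (clonal fraction 0.6, subclonal CCF ~ U(0.2, 0.8), diploid driver
loci so the multiplicity is known), a Poisson(30) benign mutation
background for TMB, and log-normal FPKM expression in which each feature's
signature genes load positively (U(0.5, 1.5)) on a latent per-sample axis.
Planted effects act on the latent axes — summed over the sample's altered
drivers plus Gaussian noise (sd 1.0, correlation 0.3 between the
anti-tumour axes CYS/ICR/TIS) — so quartile discretization induces the
ordinal association the screen should find. Everything is deterministic
given the seed.

What the generator does **not** emulate: mutational signatures and
hotspot-position realism, linkage or mutual exclusivity between drivers,
subclonal phylogenies, copy-number-driven expression dosage, batch effects,
or signature-gene overlap between features. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean causal
model, not robustness to the full messiness of real tumour data.

## Problem sizes used in validation

The packaged validation runs use deliberately desk-scale cohorts: the
regression-count contract uses 32 types × 30 samples with the default
6-driver catalog; selection calibration uses single-type cohorts of 200
samples with a 3-driver catalog (effect size 1.5 on the latent scale);
clonality recovery uses 300 mutations per condition at depths 80–140. The
study-scale headline numbers of the motivating analyses (hundreds of TIME
drivers across thousands of samples) depend on full public cohorts and
curated catalogs and are outside what synthetic desk-scale runs can or
should reproduce.
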