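# Methods

## The problem

Genomic selection programs routinely need to predict the performance of a
*complete family* of lines — a biparental cross or a half-sib pool — that has
been genotyped but not yet phenotyped, using phenotyped lines from other
families. Whenever the held-out family's marker distribution differs from
the training families' (founder effects, population substructure, array
ascertainment), the genomic relationship matrix G misrepresents the test
family's relatedness to the training set, and GBLUP predictions degrade.

The method implemented here tackles this as a covariate-shift problem.
For each held-out family it (1) trains an *adversarial* classifier to
distinguish the held-out family from the training families using only
the markers, (2) scores each marker's contribution to that distinction
with a shadow-feature relevance engine, and (3) builds a weighted
relationship matrix in which the most family-discriminating markers are
attenuated. The weighted matrix then drives an otherwise unchanged
GBLUP fit.

## Model

Phenotypes follow the standard multi-environment GBLUP decomposition

    y_ij = mu + E_i + g_j + gE_ij + e_ij

with environments E_i as fixed effects, line effects
g ~ N(0, sigma2_g G), a genotype-by-environment term with
compound-symmetry covariance sigma2_gE (Z_E Z_E' ⊙ Z_g G Z_g'), and
i.i.d. residuals. G = MM'/p, where M is the matrix of centered
markers scaled by the population standard deviation (divisor n), so
every column of M has sum of squares n and diag(G) averages exactly 1.
Single-environment data reduce to y = mu + g + e automatically.

### Marker weighting

For a held-out family f, a fictitious response labels its lines 1 and
all other lines 0. The shadow-feature engine then runs T iterations
(default 20); each iteration appends an independently permuted copy of
every marker column, fits a random forest (default 500 trees,
sqrt(2p) features per split) and records impurity importances. Two
quantities come out of this:

* **Relevance decisions** (reported, never used for weighting): a
  feature scores a *hit* when it beats the maximum shadow importance of
  the iteration; hit counts are tested one-sided against
  Binomial(T, 1/2) at alpha = 0.01 and labelled Confirmed / Tentative /
  Rejected.
* **Importance scores (IS)**: the mean raw importance of each marker
  divided by the mean raw importance of *its own shadow*, with a
  pseudocount c = 1/(2p) in both numerator and denominator, truncated
  below at 1. The per-marker shadow shares the marker's allele
  frequency, so the ratio cancels the variance bias of impurity
  importances (low-MAF markers get few splits whether or not they carry
  signal — inverting raw importances would systematically upweight
  them). Truncation at parity encodes that a marker no more important
  than its own noise copy carries no mismatch information; without it,
  sampling noise among null markers is amplified by the inversion that
  follows. The pseudocount is the importance share of an average
  feature, damping ratios of rarely used markers toward parity.

Weights are the normalized inverses, w = Inv_IS * p / sum(Inv_IS) with
Inv_IS = 1/IS, so sum(w) = p and strongly discriminating markers get
small weights. Scores at or below eps = floor_fraction x median
positive score (floor_fraction default 1e-3) are floored at eps; if no
score is positive the weights degenerate to uniform and the weighted
method reduces *exactly* to GBLUP — the intended behavior when there is
no train/test mismatch to correct. The weighted matrix is
G* = MDM'/p with D = diag(w_1^2, ..., w_p^2); weights are squared in D
while w itself (not w^2) is normalized to sum p.

### Fitting

Both G and G* enter the same eigenbasis Gibbs sampler. Each random
term's observation-level kernel K_r = V_r Lambda_r V_r' is
eigendecomposed once (components with eigenvalues below 1e-9 of the
largest are dropped); the term is sampled as u_r = V_r delta_r with
independent delta_rk ~ N(0, sigma2_r lambda_rk), which makes the full
conditional of delta_r diagonal and a sweep O(n k). Fixed effects take
flat priors (joint Gaussian update via a prefactored Cholesky);
variances take scaled-inverse-chi-square priors with 5 degrees of
freedom and scales derived from the sample variance of the observed
response, assigning R^2 = 0.5 to the random terms split equally —
an ordinary weakly-informative default for this model class. Masked
(prediction-set) responses are drawn from their full conditional every
sweep; the reported prediction is the posterior mean of the linear
predictor mu + E + g + gE at the masked cells, excluding the residual
draw.

Defaults: 10 000 iterations, 2 000 burn-in, thinning 5. All randomness
flows from one seeded generator, so runs are bit-reproducible; with unit
weights G* equals G bit-for-bit and the two methods produce identical
chains under a shared seed. Reduced chains (3 000 / 500, thinning 1)
are used in the simulation studies; thinning is disabled there because
predictions are running means and more retained draws only reduce Monte
Carlo error (measured chain-seed variability of a per-family
correlation: about ±0.01).

### Evaluation

Leave-one-family-out: each family is masked once, G or G* is built on
all lines, the model is fit per trait, and MSE, Pearson correlation
(COR) and NRMSE (root-MSE over the mean observed value) are computed on
the held-out family's observations pooled across environments, then
averaged across traits. Environments are pooled within a family rather
than scored separately — a documented choice. Relative efficiency is
GBLUP/AB for the error metrics and AB/GBLUP for COR, so RE > 1 always
favors the weighted method. The across-family (AF) row is the
arithmetic mean of per-family metrics and the arithmetic mean of
per-family REs — *not* the ratio of AF metrics; the bundled reference
table (`abweight/resources/reference_family_metrics.csv`) pins this
convention: recomputing REs and AF rows from the published per-family
metric columns reproduces the published values to three decimals.
Families with undefined COR (fewer than 3 observations or constant
vectors) are excluded from COR averages but kept for MSE and NRMSE.
Both methods always share fold seeds so RE differences reflect G vs G*
only.

## Synthetic data

`simulate_families` emulates a multi-family, multi-environment trial
with a controllable marker-distribution mismatch. Marker allele
frequencies are drawn once from Beta(2, 2); lines are independent
Hardy–Weinberg draws from their family's frequency vector. The first
family's frequencies are shifted by +delta (clipped to [0.05, 0.95]) at
a designated set of mismatch markers, recorded in the metadata sidecar.
With delta = 0 every family is an exchangeable sample from one genotype
distribution — a two-sample allele-frequency test flags only the
nominal fraction of markers — so the adversarial classifier has nothing
real to find and the weighting stays near uniform.

The trait is polygenic: by default every non-mismatch marker is causal
with a standard-normal effect (450 of 500 markers), emulating the
yield-type traits this model class targets; the genetic values are
rescaled so their realized variance equals h2 (default 0.5). The
mismatch set is deliberately non-causal — it models group-private
structure (drift, ascertainment) orthogonal to the trait, which is the
regime where down-weighting is the right move. Environment main
effects, independent line-by-environment deviations (variance
`gxe_fraction`) and Gaussian residuals complete the phenotype; the
default intercept of 10 keeps observed means positive so NRMSE is
well defined. Monomorphic markers are dropped before output, and the
metadata records the surviving mismatch and QTL identifiers.

What this generator does **not** emulate: linkage disequilibrium (loci
are independent, so shifted markers never tag causal variants),
pedigree structure within families (lines within a family are
exchangeable draws, not full sibs — there is no Mendelian-segregation
kinship signal for the model to exploit), selection, and multi-trait
genetic correlations. Consequences for interpretation: passing tests
show the weighting detects and attenuates planted frequency shifts and
that this never *hurts* under no mismatch; they cannot show the size of
the real-data gains, which in structured breeding populations flow
partly through LD and family relatedness channels absent here. In this
LD-free setting the planted shift damages the within-family ranking
only mildly — most of its effect on G is a family-level offset that
Pearson correlation ignores — so the measured RE_COR advantage of the
weighted method is small relative to its replicate-to-replicate noise
(the within-family correlation of 30 lines shifts by ~0.05 under even a
2% perturbation of G). The simulation study in the acceptance battery
reports exactly this: reliable weight separation (flagged markers
down-weighted in essentially every replicate) with an across-family
RE_COR advantage that fluctuates around parity.

## Numerical and design notes

* Dosages outside {0, 1, 2} and missing cells are rejected, never
  imputed; monomorphic markers are removed before both methods so p is
  identical for G and G*.
* Row order everywhere follows first appearance in the genotype file.
* Kernels are accepted as PSD down to -1e-8 of the top eigenvalue;
  non-finite variance draws abort the chain with the iteration number.
* The importance floor (floor_fraction, default 1e-3 of the median
  positive score) exists for generic score vectors; shadow-relative
  scores are already >= 1, so it binds only for degenerate inputs.
* Boruta decisions use no multiplicity correction (one-sided binomial
  at alpha = 0.01 per feature), matching the classical procedure; they
  are diagnostic output.
* Per-family adversarial runs are re-seeded as seed + family index;
  LOFO folds re-seed the sampler the same way, keeping the two methods'
  chains aligned.
* Problem sizes in the test battery and acceptance script (forests of
  100–250 trees in the simulation studies, 3 000-iteration chains,
  6–10 scenario replicates) are scaled-down study sizes chosen for a
  single-CPU desk run; defaults in the API remain the full-size ones.

## Known limitations

* The weighting assumes the discriminating markers are *not* the causal
  ones; when family-private structure is itself causal (as in true
  biparental families, where segregating markers carry the within-family
  kinship signal), down-weighting discriminators removes signal, and
  the method can underperform plain GBLUP. The generator's founder-free
  design deliberately stays in the favorable regime.
* The sampler is single-trait; multi-trait tables are fit one trait at
  a time and averaged.
* NRMSE is undefined for non-positive observed means and is reported
  missing in that case.
* Per-family RE of correlations is numerically unstable when the
  baseline correlation is near zero; across-family averages inherit
  that instability at small family counts.
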