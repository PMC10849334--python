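# abweight

Adversarial marker weighting for within-family genomic prediction.

`abweight` is for breeders and quantitative geneticists who need to
predict the phenotypes of a **complete, unphenotyped family** from other
families' data. When the held-out family's marker distribution differs
from the training families' (founder effects, substructure,
ascertainment), the genomic relationship matrix G = MM'/p misstates the
test family's relatedness and GBLUP predictions suffer. This package
detects that mismatch with an adversarial classifier, localizes it to
markers with a shadow-feature (Boruta-style) relevance engine, and
attenuates the offending markers in a weighted relationship matrix
G\* = MDM'/p that drives an otherwise unchanged GBLUP fit.

## Method in brief

For each held-out family *f*:

1. **Adversarial labels** — replace the phenotype with a fictitious
   response: 1 for lines of family *f*, 0 for all other lines.
2. **Shadow-feature relevance** — repeatedly fit a random forest to the
   markers plus permuted shadow copies of every marker; score each
   marker's importance relative to its own shadow (IS ≥ 1, parity = no
   signal), and record Confirmed/Tentative/Rejected decisions from a
   binomial test on how often a marker beats the best shadow.
3. **Inverse-importance weights** — w = Inv_IS · p / Σ Inv_IS with
   Inv_IS = 1/IS, so Σw = p and the most family-discriminating markers
   get the smallest weights; G\* = MDM'/p with D = diag(w²).
4. **GBLUP** — fit y_ij = μ + E_i + g_j + gE_ij + ε_ij with
   g ~ N(0, σ²_g G\*), G×E through a compound-symmetry kernel
   (Z_E Z_E' ⊙ Z_g G\* Z_g'), by an eigenbasis Gibbs sampler with the
   held-out family's phenotypes masked; predictions are posterior means
   of the linear predictor.

Evaluation is leave-one-family-out with MSE, Pearson correlation (COR)
and NRMSE, plus relative efficiencies RE_MSE and RE_NRMSE
(GBLUP/weighted) and RE_COR (weighted/GBLUP); RE > 1 favors the
weighted method. Across-family (AF) rows are arithmetic means of
per-family metrics and of per-family REs.

## Worked example

```python
import numpy as np
from abweight import BorutaConfig, MCMCSettings, ab_weights, aggregate_report, lofo_cv
from abweight.synthetic import SimConfig, simulate_families

config = SimConfig(n_families=4, lines_per_family=20, p=200, n_qtl=150,
                   mismatch_markers=30, mismatch_delta=0.4, seed=7)
dataset, meta = simulate_families(config)

boruta = BorutaConfig(n_iterations=10, trees_per_forest=150, seed=7)
mcmc = MCMCSettings(n_iter=2000, burn_in=500, thin=1, seed=7)

weights = ab_weights(dataset, "F1", boruta)
flagged = np.isin(dataset.markers.marker_ids, meta["mismatch_markers"])
print(f"mean weight, shifted markers:   {weights.w[flagged].mean():.3f}")
print(f"mean weight, unshifted markers: {weights.w[~flagged].mean():.3f}")

gblup = lofo_cv(dataset, "gblup", boruta_config=boruta, mcmc=mcmc, seed=7)
ab = lofo_cv(dataset, "ab", boruta_config=boruta, mcmc=mcmc, seed=7)
report = aggregate_report(gblup, ab, dataset_name="demo")
print(report.rounded()[["Family", "COR_GBLUP", "COR_AB",
                        "RE_MSE", "RE_COR", "RE_NRMSE"]].to_string(index=False))
```

prints

```
mean weight, shifted markers:   0.450
mean weight, unshifted markers: 1.097
Family  COR_GBLUP  COR_AB  RE_MSE  RE_COR  RE_NRMSE
    F1      0.124   0.221   1.064   1.784     1.032
    F2      0.579   0.513   0.985   0.886     0.993
    F3      0.602   0.626   0.989   1.040     0.995
    F4      0.224   0.188   0.956   0.839     0.978
    AF      0.382   0.387   0.999   1.137     0.999
```

Family F1 carries the planted frequency shift: its markers are
down-weighted (0.45 vs 1.10), and its within-family correlation rises
from 0.124 to 0.221 (RE_COR 1.78) while the unshifted families stay
near parity. The AF row averages the per-family metrics and REs.

The same pipeline runs from the shell:

```bash
abweight simulate --config sim.yaml --out data/
abweight run --genotypes data/genotype.csv --phenotypes data/phenotype.csv \
             --methods gblup,ab --seed 1 --out results/
```

`run` writes the per-family + AF report CSV and a manifest with every
setting needed to reproduce it.

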