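# seqvpc

Model-based heritability scores for sequencing count data.

## The problem

How much of the variation in a feature's expression (a gene, a miRNA) is
genetic? On a panel of genetically identical replicates — e.g. recombinant
inbred (RI) mouse strains, where animals of one strain share a genotype and
a controlled environment — broad-sense heritability is the fraction of
variance attributable to strain. For a Gaussian trait this is the
intra-class correlation σ²_g / (σ²_g + σ²_ε) of a one-way random-effects
model. Sequencing produces overdispersed counts, for which that additive
decomposition does not exist; the variance partition coefficient (VPC)
generalizes it:

    VPC = Var(E(y | strain)) / [ Var(E(y | strain)) + E(Var(y | strain)) ].

`seqvpc` computes the VPC per feature under three model families with a log
link and strain random intercept log μ_gs = α_g + b_gs, b_gs ~ N(0, σ²_g):

| family | variance | VPC (closed form) | upper bound |
|---|---|---|---|
| NB mixed model | μ + φμ² | (e^σ² − 1) / (e^σ² − 1 + φe^σ² + e^(−α−σ²/2)) | 1/(1+φ) as σ²→∞ |
| compound Poisson (Tweedie, 1<p<2) | φμ^p | (e^σ² − 1) / (e^σ² − 1 + φe^((p−2)α + (p²/2−1)σ²)) | 1 |
| LMM on VST/voom-transformed data | Gaussian | σ²_g* / (σ²_g* + σ²_ε*) | 1 |

and provides, per feature:

* a **boundary likelihood-ratio test** of H₀: σ²_g = 0 (the null sits on the
  parameter-space boundary, so −2 log LR ~ 0.5 χ²₀ + 0.5 χ²₁), with
  Benjamini–Hochberg q-values across features;
* **parametric-bootstrap percentile confidence intervals** for the VPC
  (NB-refit, CP-refit, or a fast VST-hybrid that simulates from the fitted
  NB model and refits with the transformed-LMM pipeline);
* **simulation studies** (generators plus drivers) that measure RMSE, bias,
  AUC, type-I error, power, and interval coverage of all methods under
  NB- or CP-generated data.

Marginal likelihoods are evaluated by mode-recentered Gauss–Hermite
quadrature in numba-compiled kernels, so whole-dataset fits (thousands of
features) take seconds to minutes on one core.

## Worked example

```python
import numpy as np
from seqvpc import *

rng = np.random.default_rng(7)
design = make_design(20, 3)                       # 20 strains x 3 replicates
params = draw_feature_parameters(ParameterConfig(), 60, rng, model="nb")
truth = SimulationTruth(params, design, "nb")
cm = simulate_dataset(truth, rng)

cm = filter_low_expression(cm, min_count=10, min_samples=5)
table = heritability_table(cm, methods=("nb", "vst"))
nb = table[table.method == "nb"]
print(nb[["feature_id", "vpc", "vpc_upper_bound", "lrt_stat", "p_value", "q_value"]]
      .head(5).to_string(index=False))
print("features kept:", cm.n_features, " significant at FDR 0.05:",
      int((nb.q_value < 0.05).sum()))
```

prints

```
feature_id      vpc  vpc_upper_bound   lrt_stat      p_value      q_value
    F00000 0.913968         0.914055 122.977073 7.053479e-29 1.410696e-27
    F00001 0.659615         0.659616  75.925361 1.472961e-18 4.651454e-18
    F00002 0.701521         0.701529 129.270237 2.959297e-30 8.877890e-29
    F00003 0.591571         0.591723  51.868731 2.966894e-13 5.562927e-13
    F00004 0.830738         0.830870  99.028363 1.244556e-23 9.334169e-23
features kept: 60  significant at FDR 0.05: 56
```

Reading the first row: under the NB mixed model an estimated 91.4% of
feature F00000's variance is attributable to strain. The `vpc_upper_bound`
column is the largest VPC the NB model allows at the fitted dispersion —
here the estimate sits essentially at its ceiling, a reminder that NB
scores of overdispersed features must be read against their bound rather
than against 1. The LRT statistic of 123 on the 50:50 χ² mixture gives
p ≈ 7e-29: heritability is decisively nonzero. 56 of 60 simulated features
are declared heritable at FDR 0.05 (the generator planted 10% null
features).

A confidence interval for one interesting feature:

```python
from seqvpc import NegativeBinomialMixedModel, bootstrap_ci
fit = NegativeBinomialMixedModel(cm.feature("F00000"), cm.strain_of_sample).fit()
print(fit.vpc.vpc, bootstrap_ci(fit, "nb", B=200, rng=np.random.default_rng(1)))
```

The same pipeline runs from the shell on TSV inputs
(`counts.tsv`: features × samples; `design.tsv`: sample_id, strain_id):

```sh
seqvpc heritability --counts counts.tsv --design design.tsv --out-dir results/
seqvpc ci --counts counts.tsv --design design.tsv --feature F00000 --method cp
seqvpc simulate sim4 --model nb --method nb -g 200 --seed 1 --out-dir sim/
```

Each command writes a TSV plus a JSON manifest (inputs, flags, seeds,
version) sufficient to re-run it exactly.

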