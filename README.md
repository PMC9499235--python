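# cebp

Causal effect estimation of somatic mutations on cancer biological-process
activity, with confounding — observed and hidden — handled by a variational
autoencoder.

## The problem

Driver-gene methods built on mutation frequency or mutation–expression
association answer "which mutations co-occur with aggressive tumors", not
"which mutations *cause* the processes that make tumors aggressive" (DNA
replication, epithelial–mesenchymal transition).  The association is
distorted by confounders: other mutations in the same genome and latent
factors such as micro-environment stress that raise both a gene's mutation
probability and the process activity.

`cebp` estimates, for each candidate gene *g*, the average treatment effect
of its mutation on a per-sample activity score:

```
ATE(g) = E[ Y(m=1) − Y(m=0) ]
```

where `m` indicates mutation of *g*, `Y` is the activity outcome, and the
expectation integrates over a latent confounder `z` recovered from the
mutation background.  The package is aimed at computational cancer
biologists working from a cohort's expression matrix (FPKM-like TSV),
somatic calls (binary matrix or MAF) and a pathway gene set (GMT).

## The method

**1. Activity scoring (the outcome Y).**  For a pathway of `P` genes,
compute all pairwise Pearson correlations `r_ij` with two-sided p-values
`s_ij` (t transform, `N−2` df).  Score each gene by its significance-gated
correlation sum `score_j = Σ_{i≠j} r_ij · 1[s_ij < α]` (α = 10⁻³), keep the
`⌊P/2⌋` top-scoring "core" genes, and regress each sample's core-expression
vector `u_i` against the cohort-mean core profile `K`.  The regression
coefficient `y_i = argmin_y ‖y·u_i − K‖²= ⟨u_i,K⟩/⟨u_i,u_i⟩` is the
sample's activity (a `reversed` orientation `⟨u_i,K⟩/⟨K,K⟩` is available;
the choice is recorded in the output provenance).

**2. Causal model (CEVAE).**  The structural model is `z → x`, `z → m`,
`(z, m) → y`: a latent confounder drives the binary mutation background
`x ∈ {0,1}^K` (the 200 highest-rate genes other than the target), the
binary treatment `m`, and the continuous outcome `y`.  An inference
network `q(z|x, m, y)` (shared ELU trunk, arm-specific heads) and a
generative network `p(x|z) p(m|z) p(y|z, m)` (Bernoulli decoders; arm-gated
Gaussian outcome with fixed σ) are trained jointly by maximizing the ELBO
plus auxiliary heads `q(m|x)` and `q(y|x, m)`, using Adam
(lr 10⁻³, weight decay 10⁻⁴) with early stopping on a validation split
(70/10/20).  Counterfactual outcomes are posterior expectations of the two
outcome heads; the ATE averages their contrast over the cohort, and each
reported effect is the mean ± sd of 10 independent runs.

**3. Ranking.**  Candidate genes (top-k by mutation rate, or all genes
above a rate threshold) are ranked by replicate-mean ATE; each row also
carries a Mann–Whitney U comparison of activity between mutated and
non-mutated samples.

## Worked example

```python
import numpy as np
from cebp import CEVAE, CausalSimConfig, simulate_confounded, naive_ate

# a confounded synthetic cohort with known true effect tau = 0.5
sim = simulate_confounded(CausalSimConfig(n_samples=2000, tau=0.5, seed=1))
print(f"true effect tau      : {sim.tau_true:.3f}")
print(f"naive diff-in-means  : {naive_ate(sim.dataset):.3f}")
print(f"oracle naive bias    : {sim.naive_bias_oracle:.3f}")

est = CEVAE(latent_dim=5, hidden_width=48, hidden_depth=3, epochs=250,
            patience=20, batch_size=256, random_state=1)
est.fit(sim.dataset)
print(f"CEVAE ATE estimate   : {est.ate_:.3f}")
```

prints

```
true effect tau      : 0.500
naive diff-in-means  : 1.261
oracle naive bias    : 0.827
CEVAE ATE estimate   : 0.567
```

The unadjusted group contrast (1.261) is badly biased — the latent
confounder alone accounts for 0.827 of it — while the causal model's
estimate (0.567) lands near the planted effect of 0.5.

The same workflow is available from the shell:

```bash
cebp simulate --n-samples 2000 --taus 0.5,0.0,0.0 --seed 1 --outdir cohort/
cebp rank --mutations cohort/sim_mutations.tsv --activity cohort/sim_activity.tsv \
     --rule top_k_by_rate --k 3 --out ranking.tsv
cebp mwu --mutations cohort/sim_mutations.tsv --activity cohort/sim_activity.tsv \
     --gene CAND0
```

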