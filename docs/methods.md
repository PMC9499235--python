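# Methods

## Scope and model

`cebp` estimates the average treatment effect (ATE) of a somatic mutation
on a per-sample biological-process activity score.  The assumed structural
model has four variables per sample: a latent confounder `z ∈ R^d`, the
observed mutation background `x ∈ {0,1}^K` (a proxy for `z`), the binary
treatment `m` (mutation status of the target gene) and the continuous
outcome `y` (process activity).  Arrows: `z → x`, `z → m`, `(z, m) → y`.
Identification rests on two assumptions:

* **Proxy sufficiency.**  The mutation background must actually carry
  information about the latent confounder.  If `x` is nearly independent
  of `z`, no estimator can separate the effect of `m` from the effect of
  `z`, and the ATE estimate degrades toward the naive group contrast.
  This is a property of the data, not of the optimizer; the synthetic
  benchmark makes the proxies informative on purpose (see below).
* **Overlap.**  Both treatment arms must be populated at every relevant
  confounder value; the pipeline enforces a coarse version via the ≥1%
  mutation-rate floor for treatment and confounder genes.

## Activity scoring

For a pathway of `P` genes on `N` samples:

1. Pairwise Pearson correlations with two-sided p-values from the exact
   t transform `t = r·√((N−2)/(1−r²))` on `N−2` df.  Genes with zero
   variance get `r = 0`, `p = 1` against every partner — they can never
   pass the significance gate — rather than propagating NaNs.
2. Per-gene score: the **signed** sum of that gene's correlations over
   partners significant at `α` (default 10⁻³).  The diagonal is excluded;
   including it would add a constant `1` to every score and cannot change
   the ranking.  A strongly anti-correlated hub therefore lowers its own
   score; the signed form is the method's definition, and for coherently
   co-expressed pathways (the intended use) the distinction rarely matters.
3. Core set: the `⌊P/2⌋` highest-scoring genes.  Ties are broken by
   ascending gene index (stable sort) so selection is deterministic.
4. Activity: each sample's core vector `u` is regressed against the
   cohort-mean core profile `K`.  Two orientations exist and differ
   materially:
   * `as_printed` (default): `y = argmin ‖y·u − K‖² = ⟨u,K⟩/⟨u,u⟩`.
     Samples expressing the core genes *more* strongly score *lower*
     (exactly `y(c·u) = y(u)/c`).
   * `reversed`: `y = argmin ‖u − y·K‖² = ⟨u,K⟩/⟨K,K⟩`, which is
     monotone-increasing in expression (`y(c·u) = c·y(u)`).

   The default is the literal objective; the orientation used is recorded
   in the activity provenance, and downstream effect signs must be read
   against it.  Both are closed forms; a zero denominator (all-zero sample
   or profile) raises an error naming the degenerate side.

## The causal model

**Inference network.**  `q(z|x, m, y)` is a diagonal Gaussian.  A shared
ELU trunk `g(x, y)` feeds two arm-specific heads (one per treatment arm);
each head emits per-dimension means and raw scales, the latter mapped
through a softplus with a 10⁻⁴ floor so posterior standard deviations are
strictly positive.  Auxiliary heads `q(m|x)` (single hidden layer) and
`q(y|x, m)` (trunk + arm heads) are trained jointly; they provide the
inference path when a sample's outcome is not yet measured
(`infer_from="x"`), while the default conditions on the observed triple.

**Generative network.**  `p(x|z)`: independent Bernoulli per background
gene with logits from a deep ELU net.  `p(m|z)`: Bernoulli whose logit
passes a final sigmoid — ELU hidden activations alone cannot produce a
valid probability, so the output nonlinearity must be sigmoidal.
`p(y|z, m)`: Gaussian with arm-gated mean `m·f_y1(z) + (1−m)·f_y0(z)` and
fixed standard deviation ε (below).  The latent prior is standard normal.

**Objective.**  Per-sample ELBO with the Gaussian KL computed in closed
form (variance reduction relative to a Monte Carlo KL; equal in
expectation), one reparameterized draw per training step, plus the
auxiliary log-likelihoods.  Training uses Adam (lr 10⁻³) with an L2-style
weight decay of 10⁻⁴ folded into the gradients, mini-batches of 128
(full-batch when smaller), a seeded 70/10/20 train/validation/test split,
at most 300 epochs, and early stopping on the validation objective with
patience 30; the parameters at the best validation epoch are returned.

**Outcome decoder variance ε.**  ε is fixed during training and acts as an
inverse weight on the outcome-reconstruction term relative to the K-dim
background reconstruction.  A unit ε is the wrong scale for activity
values (typically ≪ 1) and under-weights the `z → y` path, leaving
residual confounding in the arm heads.  Default `outcome_sd="auto"`
therefore sets ε to the residual standard deviation of an OLS fit of `y`
on `(1, m, x)` over the training split (floored at 0.05) — a standard
moment-based scale estimate that uses no ground-truth knowledge.  A fixed
positive float can be supplied instead.

**ATE.**  For every sample, `n_mc` (default 100) posterior draws are
pushed through both outcome heads; the ATE is the mean of
`ŷ(m=1) − ŷ(m=0)` over **all** N samples (the 1/N form), with a `subset`
argument to restrict to the held-out test split.  Reported effects
aggregate `n_replicates = 10` independent runs (seeds `base_seed + r`),
as mean and sample standard deviation.

**Network sizing.**  Defaults are 3 hidden ELU layers of width 200 for the
deep paths — realized for `q(z|·)` and `q(y|·)` as a trunk providing
depth−1 activated layers plus a one-hidden-layer head — and a single
hidden layer for both treatment networks.  The effect-recovery tests and
the acceptance script run width 48 (32 for the ranking cohort), 250
epochs, patience 20, batch 256: on the benchmark sizes below these reach
the same estimates as wider settings at a fraction of the cost, and all
problem sizes used are stated here as the package's own test protocol.

## Synthetic benchmark

`simulate_confounded` draws exactly from the assumed structural model:
`z ~ N(0, I_d)`; `x_ij ~ Bern(σ(a_j + b_j·z_i))` with per-gene baselines
`a_j ~ U(−4.5, −0.5)` (marginal mutation rates ≈ 1–40%, honoring the rate
floor) and loadings `b_j ~ N(0, (3/√d)² I)`; `m_i ~ Bern(σ(c·z_i))` and
`y_i = τ·m_i + w·z_i + N(0, 0.5²)`, with `c` and `w` unit-scale vectors
along the same direction of `z` so the confounding is real rather than
orthogonal by chance.  The true ATE is exactly τ by construction (the
outcome is linear-Gaussian precisely so that analytic checks exist), and
the bias of the naive difference-in-means is measured by a large Monte
Carlo evaluation of the generative law (≈ 0.83 under the defaults,
comfortably past the ≥ 0.2 "strongly confounded" bar).  The proxy loading
scale of 3 makes the background informative about `z`, which is the
regime the method assumes; with weak proxies (scale 1) roughly a third of
the confounder information is simply absent from the data and a residual
bias of ≈ 0.1–0.3 is information-theoretically unavoidable.

Default benchmark sizes: n = 2000 samples, K = 50 background genes,
d = 5 latent dimensions, τ = 0.5 — a cohort on the scale of the larger
TCGA-style datasets but small enough to train in seconds per run on one
CPU.

`simulate_pathway` plants a block of `⌊P/2⌋` core genes sharing a
`N(0,1)` per-sample factor (loading 4.5, noise sd 0.5, baseline 20);
non-core genes are independent noise.  Nonnegativity is achieved by a
constant shift, never truncation, so all correlations are preserved
exactly.  `simulate_mutation_cohort` composes several candidate treatment
genes (each confounded by the same `z`, one carrying a real effect) with
the background block, written in exactly the formats the readers accept.

**What the generator does not emulate:** mutational signatures, gene
length effects, panel/coverage artifacts, cohort substructure, nonlinear
outcome surfaces, or multi-gene (bundled) effects.  Passing the recovery
tests shows the estimator removes confounding *of the kind the model
assumes*; it is not evidence about robustness to model misspecification
on real cohorts.

## Preprocessing rules

* Samples are restricted to the expression/mutation intersection and
  lexicographically sorted (determinism independent of input order).
* Non-expressed genes are dropped when their **cohort mean** falls below
  the threshold (default 10 FPKM-like units).  A per-sample "less than 10
  anywhere" reading would discard nearly every gene; an `all_below`
  variant (drop only if no sample reaches the threshold) is available.
* MAF binarization counts every variant class except `Silent`
  (configurable), ORs repeated records, and is invariant to record order.
* Candidate rules: top-k by mutation rate or rate ≥ threshold; ties by
  ascending gene id.  Per-gene confounder blocks take the 200 (default)
  highest-rate genes excluding the target, all at rate ≥ 1%, with a
  logged warning when fewer are available.
* Mann–Whitney U: midranks; exact enumeration when the smaller group has
  ≤ 8 samples and there are no ties, otherwise normal approximation with
  tie and continuity corrections.  Raw two-sided p-values are reported;
  a Benjamini–Hochberg column is an explicitly labeled optional extension.

## Numerical choices

* Networks run on a package-internal vectorized reverse-mode autodiff
  engine (validated against central finite differences); Bernoulli
  log-likelihoods use the `m·logit − softplus(logit)` form and softplus
  uses the shifted-log1p form, both stable at extreme logits.
* Glorot-uniform initialization, zero biases; all initialization, splits,
  batching and Monte Carlo draws derive from a single seeded generator
  per run, so identical config + seed reproduces results bit-for-bit.
* Ranking folds the candidate index into the replicate seed
  (`base_seed + index·n_replicates + r`) so different genes never share
  an initialization; per-gene failures (e.g. a split that loses a
  treatment arm) are logged and skipped rather than aborting a long run.
* Replicate std with one replicate is reported as 0 with a warning.

## Known limitations

* Single-gene treatments only; bundled effects of mutation sets are out
  of scope.
* No confidence intervals on individual treatment effects; uncertainty is
  summarized only as the across-replicate spread of the ATE.
* The fixed-ε Gaussian outcome assumes roughly homoscedastic activity
  residuals; heavy-tailed outcomes would call for a different decoder.
* ATE estimates inherit the activity orientation: under the default
  `as_printed` regression, positive effects mean the mutation *lowers*
  relative core-gene expression.  Use `reversed` for the increasing
  orientation and read signs accordingly.
* With weakly informative mutation backgrounds the estimator degrades
  gracefully toward (but does not reach) the naive contrast; it cannot
  manufacture information the proxies do not contain.
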