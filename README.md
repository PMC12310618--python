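# mnrmmix

Mixture multidimensional nominal response modeling of faking strategies in
high-stakes personality assessments.

## The problem

Self-report personality questionnaires used for personnel selection are
vulnerable to *faking*: applicants align their answers with what they believe
is socially desirable. Classical faking models add one continuous latent
faking dimension to the substantive traits and assume every test-taker uses
it. Real applicant pools are more heterogeneous — some respondents answer
purely from their traits, some purely from desirability, and some from a
compromise of both.

`mnrmmix` implements a confirmatory mixture extension of the
multidimensional nominal response model (MNRM) that represents these three
response strategies as structurally defined latent classes. It is aimed at
psychometricians and selection researchers who want to classify response
strategies, de-bias trait estimation under faking, and study covariates of
strategy use.

## The model

Item responses in categories k = 0..K follow a softmax over category logits,

    p(Y_ni = k | ζ_n = c) ∝ exp( (α_i ∘ s_ik)' θ_n + γ_ik^c ),

where θ_n holds the person's T substantive trait scores plus a faking score,
α_i are item slopes, γ_ik^c class-specific item-category intercepts
(γ_i0^c = 0), and s_ik fixed scoring weights: the measured trait uses the
partial-credit pattern (0, 1, …, K); the faking dimension uses per-item
category desirabilities rescaled to the common 0–6 metric.

Three latent classes differ only in which dimensions load (via a binary
slope mask): **S&F** (traits + faking, the reference class), **S-only**
(traits only) and **F-only** (faking only). Class identity is therefore
structural and no label switching can occur. Class membership is predicted
by a latent multinomial logistic regression on person covariates,

    π_nc ∝ exp(β_0c + Σ_p β_pc x_np),    β·,S&F = 0.

Estimation is Bayesian MCMC (own adaptive Metropolis-within-Gibbs sampler
with the discrete membership marginalized out; see `docs/methods.md`), with
priors α ~ N⁺(0, 2²), γ ~ N(0, 5²), θ ~ MVN(0, Σ) with unit variances and
pairwise-uniform correlations, and β ~ N(0, 2²).

Model comparison uses DIC, WAIC and PSIS-LOO (LOOIC); absolute fit uses a
posterior-predictive SRMR on item intercorrelations; classification quality
is summarized by posterior class probabilities and normalized entropy.

## Worked example

```python
import numpy as np
import mnrmmix as m

# generate one equal-thirds dataset: 300 test-takers, 3 traits x 5 items,
# 7-point scale, three covariates of class membership
design = m.SimulationDesign(items_per_trait=5, n_persons=300, condition=1, seed=1)
sim = m.simulate(design)

# fit the three-class mixture model
cfg = m.SamplerConfig(chains=2, burnin=500, iterations=1000, seed=7)
post = m.fit(sim.responses, sim.truth.weights, m.three_class_spec(),
             covariates=sim.X, config=cfg)

props, ci = m.class_proportions(post)
pe = m.point_estimates(post)
print("class proportions:", np.round(props, 3))
print("hit rate:", round(m.hit_rate(pe["zeta"], sim.truth.zeta), 3))
print("entropy:", round(m.entropy(pe["responsibilities"]), 3))
print("max R-hat:", round(post.max_rhat, 3))
```

Output from this exact script:

```
class proportions: [0.341 0.3   0.359]
hit rate: 0.933
entropy: 0.866
max R-hat: 1.114
```

The proportions recover the generating thirds to within a few points; 93% of
simulated test-takers are assigned to their true response-strategy class,
and the entropy indicates good class separation. The worst split-chain R-hat
sits just above the 1.1 rule of thumb — typical for chains this short; the
full-length defaults (4 chains, 2000 burnin, 5000 retained) push it below.

The command-line interface mirrors the library:

```bash
mnrmmix simulate --condition 1 --n 300 --items-per-trait 5 --seed 1 --out data/
mnrmmix fit --model mix --responses data/responses.csv --weights data/weights.csv \
            --covariates data/covariates.csv --seed 7 --out results/mix
mnrmmix compare results/mix results/sf
mnrmmix score-new --responses new.csv --weights data/weights.csv \
                  --fitted results/mix --out scored/
```

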