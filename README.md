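# protomix

Computational modelling of single-category dot-pattern learning: who
abstracts a prototype, who memorizes exemplars, and how strict is their
decision policy?

In the classic A/not-A dot-pattern paradigm, participants learn over feedback
rounds whether nine-dot patterns belong to category "A".  The patterns are
distortions of a hidden prototype; after training, a transfer phase without
feedback probes generalization to novel items.  `protomix` provides the full
modelling stack for this task:

- **stimuli** — Posner-style generator for the 41-pattern inventory (1
  prototype, 20 distorted members at distortion levels 4–7, 20 random
  nonmembers), with the training/transfer partition and enforced distance
  constraints (members within 6.22 grid units of the prototype in the 18-D
  stacked-coordinate norm, nonmembers beyond 12.93).
- **models** — the observation-model family.  Similarity decays
  exponentially with distance, `s_iP = exp(-c·d_iP)` (prototype) and
  `s_iEx = Σ_j exp(-c·d_ij)` (summed over training exemplars).  Endorsement
  follows `r = s/(s+k)` with criterion `k`; mixture models blend the two
  routes, `r = β·r_proto + (1-β)·r_ex`, and γ-variants scale
  `r = s^γ/(s^γ+k^γ)` for more or less deterministic responding.  A guessing
  model fixes `r = 0.5`.
- **synthetic_data** — simulated cohorts of agents whose β declines over
  training, whose sensitivity `c` rises, and whose criterion `k` differs
  between low- and high-trait groups, plus labelled recovery suites.
- **inference** — per-subject Bayesian fitting with uniform priors
  (`c ~ U(0,5)`, `k ~ U(0,1)`, `β ~ U(0,1)`, `γ ~ U(0,20)`), a two-stage
  MCMC protocol (short pilot run, posterior quantiles seed the final
  chains), split-chain Rhat diagnostics with automatic escalation, and DIC
  model comparison (`DIC = D̄ + p_D`, `p_D = D̄ − D̂`).
- **pipeline** — the adaptive training protocol (stop after ≥ 8 rounds with
  ≥ 4 rounds at 75% accuracy, cap at 14), accuracy summaries, participant
  QC filters (performance, guess-level fits, trait outliers), recovery
  experiments and run reports.

A scikit-learn style estimator, `BayesianEndorsementModel`, wraps a fit for
use with sklearn pipelines and `clone`.

## Worked example

Simulate transfer data from a known mixture agent and ask which strategy
explains it best:

```python
import numpy as np
from protomix import (build_stimulus_set, ItemDistances, EndorsementData,
                      ParameterSet, predict_endorsement, fit_model,
                      select_model, FAST_CHAINS)

sset = build_stimulus_set(rng_seed=7)
dists = ItemDistances.from_stimulus_set(sset, "transfer")

truth = ParameterSet(c=1.5, k=0.3, beta=0.5)
r = predict_endorsement("MIX", truth, dists.d_proto, dists.d_ex)
rng = np.random.default_rng(0)
data = EndorsementData.from_counts(dists.item_ids,
                                   rng.binomial(8, r).astype(float),
                                   np.full(41, 8.0))

fits = [fit_model(m, data, dists, chains=FAST_CHAINS, seed=1)
        for m in ("MIX", "PROTO", "EX")]
guess = fit_model("GUESS", data, dists)
for f in fits + [guess]:
    means = {p: round(v, 3) for p, v in f.posterior_mean.items()}
    print(f"{f.model:6s} DIC={f.dic.dic:8.2f}  converged={f.converged}  {means}")
report = select_model(fits, guess)
print("best model:", report.best_model, "| guess-level:", report.guess_level)
```

Output:

```
MIX    DIC=  166.25  converged=True  {'c': 1.169, 'k': 0.469, 'beta': 0.472}
PROTO  DIC=  195.82  converged=True  {'c': 0.301, 'k': 0.795}
EX     DIC=  176.78  converged=True  {'c': 0.927, 'k': 0.942}
GUESS  DIC=  454.70  converged=True  {}
best model: MIX | guess-level: False
```

The mixture model wins by ~10 DIC points over the best single-route model,
its posterior-mean β ≈ 0.47 recovers the generating weight 0.5, and every
model beats guessing by far (the parameterless guessing DIC on 41 items × 8
rounds is the constant 2·328·ln 2 ≈ 454.70).  `k` and `β` trade off against
each other to a degree, which is why the criterion estimate sits above its
generating value while the 95% credible interval still covers it.

A command-line layer mirrors the library:

```bash
protomix generate --seed 3 --out stim/
protomix simulate --seed 4 --n-per-group 10 --out cohort/
protomix fit cohort/trials.csv --stimuli cohort/stimuli.json --out fits/
protomix compare fits/fits.csv --out selection/
protomix report cohort/
```

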