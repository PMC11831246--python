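# Methods

## Task and stimulus model

The paradigm is single-category (A/not-A) dot-pattern classification.  A
prototype of nine dots is placed uniformly on integer grid points in the
central 30×30 region of a 50×50 grid-unit canvas.  Category members are
distortions of the prototype: each dot is displaced independently by a
radial jitter with uniform angle and Rayleigh-distributed radius.  The
Rayleigh scale is indexed by distortion level, DL4–DL7 = {0.7, 0.9, 1.1,
1.3} grid units by default, giving an expected per-dot displacement that is
strictly increasing in level.  The exact level-to-magnitude tables of the
classical area-displacement construction are not uniquely determined, so the
scale table is a configurable parameter of the generator rather than a claim
of fidelity; what is enforced is the structure that matters downstream.

Nonmembers are unrelated random patterns drawn by the same placement rule as
the prototype.  Pattern distance is the Euclidean norm in the stacked 18-D
coordinate space with dots matched by index (distortion preserves index, so
no assignment problem arises).  Two constraints are enforced by rejection
sampling (at most 10,000 attempts per item, then a loud failure — the
constraints are never silently relaxed):

- every member lies within `member_dmax = 6.22` of the prototype;
- every nonmember lies at least `nonmember_dmin = 12.93` away.

Whether these published thresholds refer to 18-D norms or per-dot averages
is not documented; the 18-D norm is adopted and both thresholds are exposed
in `GeneratorConfig`.  Under the default geometry random nonmembers land
30–60 units from the prototype, so the nonmember floor is loose; members
are genuinely constrained (acceptance ≈ 0.85 at DL7).

The inventory is 41 patterns: the prototype, 12 training members (4 each of
DL5/DL6/DL7), 12 training nonmembers, 8 novel members (2 each of DL4–7) and
8 novel nonmembers.  Training rounds present the 24 training items (never
the prototype); transfer rounds present all 41.

## Observation models

Similarity decays exponentially with distance, scaled by sensitivity `c`:

- prototype route: `s_iP = exp(-c · d_iP)`
- exemplar route: `s_iEx = Σ_{j∈A} exp(-c · d_ij)` over the 12 training
  exemplars; a training item's self-term contributes exactly 1.

Endorsement probability uses a Luce-style criterion rule `r = s/(s+k)`,
`k ∈ (0, 1]` (larger k = stricter).  The family:

PROTO and EX use one route; MIX blends them,
`r = β·r_proto + (1-β)·r_ex` with `β ∈ [0, 1]`; MIX-2c gives each route its
own sensitivity (`c_proto`, `c_ex`); γ-variants (EX-γ, MIX-γ, MIX-2c-γ) use
`r = s^γ/(s^γ + k^γ)`.  The published form of the γ rule is written for the
exemplar route only; whether γ also scales the prototype component of the
mixture variants is an open choice.  We default to scaling **both**
components (`gamma_scope="both"`) for symmetry — at γ=1 every variant
reduces exactly to its restricted version either way — and expose
`gamma_scope="exemplar_only"` as a switch.  The guessing model fixes
`r = 0.5` for every item and has no free parameters.

### Likelihood

No observation distribution is uniquely implied by fitting "endorsement
rates", so we use the minimal proper choice: Bernoulli per binary training
response, and for transfer counts over `n` rounds the Binomial written in
product-Bernoulli form, `ℓ = Σ_i y_i·ln r_i + (n_i − y_i)·ln(1 − r_i)`.
The binomial coefficient is omitted; it is constant in the parameters and
cancels from all model comparisons, and this convention makes the guessing
deviance the exact closed form `2 · N · ln 2` for `N` observed trials
(454.70 for 41 items × 8 rounds).  Timeout trials drop out of the
likelihood, mirroring their exclusion from accuracy.  Probabilities are
clipped to `[1e-12, 1 − 1e-12]` inside the likelihood only, never in
reported values.

## Bayesian fitting

Uniform priors: `c, c_proto, c_ex ~ U(0, 5)`, `k ~ U(0, 1)`,
`β ~ U(0, 1)`, `γ ~ U(0, 20)`.  The sampler is a vectorised random-walk
Metropolis on the prior box: Gaussian joint proposals, out-of-box proposals
rejected (the uniform prior's density cancels inside the box), per-chain
proposal scales adapted toward ≈ 30% acceptance during burn-in only, so the
post-burn-in kernel is fixed and valid.  The chain protocol:

1. **Stage 1** — 4,000 iterations, 500 burn-in, 4 chains, initial values
   drawn from the prior.
2. The pooled stage-1 posterior's {2.5, 25, 50, 75, 97.5}% quantiles are
   computed; the four final chains start from the {2.5, 25, 75, 97.5}%
   vectors (five quantiles, four chains: the median is dropped; the mapping
   is recorded in the fit result).
3. **Final run** — 20,000 iterations, 2,500 burn-in, 4 chains, thinning 5
   (`ChainConfig` defaults; `FAST_CHAINS` = 5,000/1,000 for simulation
   studies).
4. Convergence is judged by the classic split-chain Gelman–Rubin statistic
   with threshold 1.1 (configurable).  If any parameter exceeds it, the run
   escalates once to 100,000 iterations and refits; persistent
   non-convergence is *reported* (`converged=False`, excluded from model
   ranking), never raised — low-information fits such as a single 24-trial
   training round must degrade gracefully.

Everything is deterministic given the fit seed (sub-streams are spawned per
stage from one `SeedSequence`).  Effective sample size uses FFT
autocorrelation with Geyer-style initial-positive-sequence truncation.

Model fit is `DIC = D̄ + p_D` with `D̄` the mean posterior deviance, `D̂`
the deviance at the posterior means and `p_D = D̄ − D̂` (the classic
mean-deviance form, not the half-variance variant).  The guessing DIC is
computed analytically with `p_D = 0`.  Model selection ranks converged fits
by DIC; near-ties (ΔDIC < 0.5) break toward fewer free parameters, and a
subject is flagged *guess-level* when the best model fails to undercut the
guessing DIC by at least 2 (a conventional weak-evidence threshold; both
constants are arguments).

## Synthetic cohorts

Agents respond generatively from the model family.  Parameter trajectories
are linear in round index between template start/end values (the reported
trends are monotone; no shape information exists beyond that), with the
transfer phase using the end values.  Default templates (MIX agents):

| group   | β           | c            | k            |
|---------|-------------|--------------|--------------|
| AQ_low  | 0.80 → 0.20 | 0.15 → 0.35  | 0.20 → 0.10  |
| AQ_high | 0.80 → 0.45 | 0.15 → 0.35  | 0.30 → 0.18  |

These calibration constants encode the qualitative dynamics to be emulated:
β declines (more slowly in the high-trait group), sensitivity rises in both
groups, the criterion loosens over training but stays stricter in the
high-trait group.  The magnitudes were chosen once so that default agents
are competent (most reach the stop criterion and exceed 75% accuracy in
their final round) while the groups separate in member accuracy and not in
nonmember accuracy; they are config values, not empirical claims.  Timeouts
occur independently per trial at rate 0.02 (no timeout mechanism is
documented, so independence is the simplest model).  Trait scores are drawn
per group (Normal(11, 4) vs Normal(23, 5), clipped to the 0–50 range) and
used only by the QC trait-outlier filter.

What the simulator deliberately does **not** emulate: reaction times,
within-agent parameter noise around the trajectory, item-specific
difficulty, sequential (feedback-driven) learning dynamics, or any neural
signal.  Passing recovery tests therefore demonstrate that the inference
machinery is correct and well calibrated *for data generated by the model
family itself* — they cannot certify behaviour on human data, where the true
generative process is unknown.

Recovery suites simulate transfer datasets (41 items × 8 rounds by default)
on a parameter grid.  Where a published calibration example fixes only part
of the grid, the remaining generating values are `c = 1.5`, `k = 0.3`.

## Pipeline conventions

- **Stop rule**: training ends once ≥ 8 rounds are completed with ≥ 4
  rounds at ≥ 75% accuracy, else after round 14.  "Last training block" is
  interpreted as the final completed round.
- **QC**: a subject is excluded for *low performance* only when both the
  last training round and the transfer average fall below 75%; for
  *guess-level* fits per the selection rule above; for a *trait outlier*
  score above the clinical cutoff 32 or more than 3 SD above the cohort
  mean.
- **Summaries**: accuracies exclude timeouts from denominators;
  distortion-level summaries are restricted to members (DL is undefined
  elsewhere); training-vs-novel contrasts are restricted to DL5–7, the
  levels present in both item pools.
- **Similarity export**: per correctly categorized member trial, `s_proto`
  and `s_ex` at the posterior-mean parameters (mixture fits add the
  β-weighted `s_mix`); non-converged fits are refused.  These vectors are
  the parametric modulators a neural analysis would consume; on this
  stimulus geometry the two are strongly positively correlated over training
  members, which is exactly why the mixture blend (a single modulator) is
  provided.

## Numerical and design notes

- Problem sizes in the test suite (20 replicates per recovery cell,
  `FAST_CHAINS` schedules) are the package's default simulation-study scale;
  they hold Monte-Carlo error comfortably below the margins asserted.
- Degenerate inputs: zero-variance draws give Rhat = 1 by convention; a
  point posterior gives `p_D = 0`; all-timeout data raise before sampling;
  more than 10% non-finite deviance draws abort the DIC (fewer are dropped
  with a warning).
- The sklearn estimator encodes the geometry as a feature matrix (column 0
  = prototype distance, remaining columns = exemplar distances) so fits
  compose with `clone`, pipelines and model selection; it delegates to the
  same `fit_model` core.

## Known limitations

- The distortion scheme approximates the classical construction's *shape*
  (radial, level-indexed) but not its exact displacement tables.
- Random nonmembers are far from the prototype, so the nonmember distance
  floor is rarely binding and nonmember items carry little information about
  `c`; sensitivity is mainly identified through members, and its posterior
  is wide whenever large `c` values are observationally equivalent.
- β and k trade off in mixture fits on single-category data; rank-order
  recovery of β is excellent, point recovery is shrunken toward the prior
  middle at this trial count.
- DIC is the only fit index implemented (by design); WAIC/LOO and
  hierarchical pooling are out of scope.
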