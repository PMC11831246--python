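"""Bayesian fitting of the observation models.

Each model is fitted per subject and dataset with uniform priors on a
bounded parameter box (c ~ U(0,5), k ~ U(0,1), beta ~ U(0,1),
gamma ~ U(0,20)) using a vectorised random-walk Metropolis sampler whose
proposal scales adapt during burn-in only.  The chain protocol is two-stage:
a short run without explicit initial values (4000 iterations, 500 burn-in,
four chains) yields posterior quantiles whose {2.5, 25, 75, 97.5}% values
initialise the four chains of the final run (20000 iterations, 2500
burn-in, thinning 5 by default).  If any split-chain Rhat exceeds the
convergence threshold, the final run is escalated once to a longer chain
(default 100000 iterations).  Model fit is measured by the deviance
information criterion, DIC = Dbar + pD with pD = Dbar - Dhat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    DiagnosticError,
    InitializationError,
    SelectionError,
)
from .models import (
    EndorsementData,
    ItemDistances,
    MODEL_FREE_PARAMS,
    ParameterSet,
    _model_name,
    log_likelihood_theta,
)

QUANTILE_LEVELS = (2.5, 25.0, 50.0, 75.0, 97.5)
#: stage-1 quantiles assigned to the four final chains (median dropped)
INIT_QUANTILES = (2.5, 25.0, 75.0, 97.5)


@dataclass
class PriorSpec:
    """Uniform prior bounds per parameter; overrides allowed per key."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "c": (0.0, 5.0),
        "c_proto": (0.0, 5.0),
        "c_ex": (0.0, 5.0),
        "k": (0.0, 1.0),
        "beta": (0.0, 1.0),
        "gamma": (0.0, 20.0),
    })

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"prior for {name!r} must have finite lo < hi")

    def box(self, model) -> tuple[np.ndarray, np.ndarray]:
        names = MODEL_FREE_PARAMS[_model_name(model)]
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi


@dataclass
class ChainConfig:
    """MCMC schedule. ``n_iter`` counts total iterations including burn-in."""

    n_chains: int = 4
    n_iter: int = 20_000
    burn_in: int = 2_500
    thin: int = 5
    init_n_iter: int = 4_000
    init_burn_in: int = 500
    escalation_iter: int = 100_000
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ConfigurationError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")


#: reduced schedule for simulation experiments (recovery suites)
FAST_CHAINS = ChainConfig(n_iter=5_000, burn_in=1_000, thin=5,
                          init_n_iter=2_000, init_burn_in=500,
                          escalation_iter=20_000)


@dataclass
class DICResult:
    dbar: float
    dhat: float
    p_d: float
    dic: float


@dataclass
class FitResult:
    """Posterior summaries of one (subject, model, dataset) fit."""

    model: str
    draws: np.ndarray  # (n_chains, n_draws, n_params), post burn-in, thinned
    param_names: tuple[str, ...]
    posterior_mean: dict[str, float]
    quantiles: dict[str, dict[float, float]]
    rhat: dict[str, float]
    ess: dict[str, float]
    dic: DICResult
    converged: bool
    escalated: bool = False
    n_iter_used: int = 0
    init_values: np.ndarray | None = None
    seed: int | None = None

    @property
    def posterior_parameters(self) -> ParameterSet:
        return ParameterSet(**self.posterior_mean)

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1]) if self.draws.size else self.draws


# ---------------------------------------------------------------------------
# diagnostics


def compute_rhat(chain_draws) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chain_draws`` is (n_chains, n_draws) for one parameter.  Chains are
    split in half; Rhat = sqrt(((n-1)/n * W + B/n) / W).  Returns 1.0 for
    degenerate (zero-variance) draws.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DiagnosticError("need >= 2 chains of draws")
    n = x.shape[1]
    if n < 10:
        raise DiagnosticError("need >= 10 post-burn-in draws per chain")
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)  # (2m, half)
    w = splits.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = half * splits.mean(axis=1).var(ddof=1)
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def compute_ess(chain_draws) -> float:
    """Effective sample size with FFT autocorrelation and Geyer-style
    initial-positive-sequence truncation, averaged across chains."""
    x = np.asarray(chain_draws, dtype=float)
    m, n = x.shape
    if n < 4:
        return float(m * n)
    xc = x - x.mean(axis=1, keepdims=True)
    if np.allclose(xc, 0):
        return float(m * n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), nfft, axis=1)[:, :n].real
    acov /= n
    rho = (acov / acov[:, :1]).mean(axis=0)  # mean autocorrelation over chains
    # sum consecutive pairs; stop at first negative pair sum
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
        t += 2
    return float(m * n / max(tau, 1.0))


# ---------------------------------------------------------------------------
# sampler


def _run_chains(model, y, nobs, d_proto, d_ex, lo, hi, n_chains, n_iter, burn_in,
                thin, rng, inits=None, gamma_scope="both", adapt_interval=50,
                target_accept=0.3):
    """Random-walk Metropolis over the prior box; returns thinned post
    burn-in draws of shape (n_chains, n_keep, p)."""
    p = len(lo)

    def loglik(theta):
        return log_likelihood_theta(model, theta, y, nobs, d_proto, d_ex, gamma_scope)

    if inits is None:
        theta = None
        for _ in range(100):
            cand = rng.uniform(lo, hi, size=(n_chains, p))
            if np.all(np.isfinite(loglik(cand))):
                theta = cand
                break
        if theta is None:
            raise InitializationError("no finite-likelihood starting point found in prior box")
    else:
        theta = np.array(inits, dtype=float).reshape(n_chains, p)
        eps = 1e-9 * (hi - lo)
        theta = np.clip(theta, lo + eps, hi - eps)
        if not np.all(np.isfinite(loglik(theta))):
            raise InitializationError("non-finite likelihood at provided initial values")

    ll = loglik(theta)
    scale = np.tile(0.1 * (hi - lo), (n_chains, 1))
    keep_iters = range(burn_in, n_iter, thin)
    n_keep = len(keep_iters)
    out = np.empty((n_chains, n_keep, p))
    accepted = np.zeros(n_chains)
    k_out = 0
    for it in range(n_iter):
        prop = theta + rng.standard_normal((n_chains, p)) * scale
        in_box = np.all((prop > lo) & (prop < hi), axis=1)
        ll_prop = np.full(n_chains, -np.inf)
        if in_box.any():
            ll_prop[in_box] = loglik(prop[in_box])
        accept = np.log(rng.random(n_chains)) < (ll_prop - ll)
        theta = np.where(accept[:, None], prop, theta)
        ll = np.where(accept, ll_prop, ll)
        accepted += accept
        if it < burn_in and (it + 1) % adapt_interval == 0:
            rate = accepted / adapt_interval
            scale *= np.exp(np.clip(rate - target_accept, -0.5, 0.5))[:, None]
            accepted[:] = 0.0
        if it >= burn_in and (it - burn_in) % thin == 0:
            out[:, k_out] = theta
            k_out += 1
    return out


def _summaries(draws, names):
    flat = draws.reshape(-1, draws.shape[-1])
    means = {n: float(flat[:, i].mean()) for i, n in enumerate(names)}
    quants = {
        n: {q: float(np.percentile(flat[:, i], q)) for q in QUANTILE_LEVELS}
        for i, n in enumerate(names)
    }
    rhat = {n: compute_rhat(draws[:, :, i]) for i, n in enumerate(names)}
    ess = {n: compute_ess(draws[:, :, i]) for i, n in enumerate(names)}
    return means, quants, rhat, ess


def compute_dic(model, data: EndorsementData, distances: ItemDistances, draws,
                gamma_scope: str = "both", min_draws: int = 100) -> DICResult:
    """DIC from retained posterior draws.

    Dbar is the mean posterior deviance (-2 log likelihood), Dhat the
    deviance at the posterior means, pD = Dbar - Dhat and DIC = Dbar + pD.
    The parameterless guessing model needs no draws: its deviance is the
    constant 2 * n_trials * ln 2 and pD = 0.
    """
    name = _model_name(model)
    d_proto, d_ex, y, nobs = distances.align(data)
    if name == "GUESS":
        d = float(2.0 * data.n_trials * np.log(2.0))
        return DICResult(dbar=d, dhat=d, p_d=0.0, dic=d)
    flat = np.asarray(draws, dtype=float)
    if flat.ndim == 3:
        flat = flat.reshape(-1, flat.shape[-1])
    if flat.shape[0] < min_draws:
        raise DataError(f"DIC needs >= {min_draws} retained draws, got {flat.shape[0]}")
    dev = -2.0 * log_likelihood_theta(name, flat, y, nobs, d_proto, d_ex, gamma_scope)
    finite = np.isfinite(dev)
    if finite.mean() < 0.9:
        raise DataError("more than 10% non-finite deviance draws")
    if not finite.all():
        import warnings

        warnings.warn("excluding non-finite deviance draws from DIC")
        dev = dev[finite]
        flat = flat[finite]
    dbar = float(dev.mean())
    theta_mean = flat.mean(axis=0)
    dhat = float(-2.0 * log_likelihood_theta(name, theta_mean, y, nobs, d_proto,
                                             d_ex, gamma_scope))
    p_d = dbar - dhat
    return DICResult(dbar=dbar, dhat=dhat, p_d=p_d, dic=dbar + p_d)


def fit_model(model, data: EndorsementData, distances: ItemDistances,
              priors: PriorSpec | None = None, chains: ChainConfig | None = None,
              seed: int = 0, gamma_scope: str = "both") -> FitResult:
    """Fit one model to one dataset under the two-stage chain protocol."""
    name = _model_name(model)
    priors = priors or PriorSpec()
    cfg = chains or ChainConfig()
    if data.n_trials < 1:
        raise DataError("no observed trials (all responses missing)")

    if name == "GUESS":
        dic = compute_dic("GUESS", data, distances, None)
        return FitResult(model="GUESS", draws=np.empty((0, 0, 0)), param_names=(),
                         posterior_mean={}, quantiles={}, rhat={}, ess={},
                         dic=dic, converged=True, n_iter_used=0, seed=seed)

    names = MODEL_FREE_PARAMS[name]
    lo, hi = priors.box(name)
    d_proto, d_ex, y, nobs = distances.align(data)
    ss = np.random.SeedSequence(seed)
    rng_stage1, rng_final, rng_esc = (np.random.default_rng(s) for s in ss.spawn(3))

    # stage 1: no explicit inits, short run
    stage1 = _run_chains(name, y, nobs, d_proto, d_ex, lo, hi, cfg.n_chains,
                         cfg.init_n_iter, cfg.init_burn_in, 1, rng_stage1,
                         gamma_scope=gamma_scope)
    pooled = stage1.reshape(-1, len(names))
    inits = np.stack([np.percentile(pooled, q, axis=0) for q in INIT_QUANTILES])
    if cfg.n_chains != len(INIT_QUANTILES):
        # repeat/truncate the quantile vectors to the requested chain count
        reps = int(np.ceil(cfg.n_chains / len(INIT_QUANTILES)))
        inits = np.tile(inits, (reps, 1))[: cfg.n_chains]

    draws = _run_chains(name, y, nobs, d_proto, d_ex, lo, hi, cfg.n_chains,
                        cfg.n_iter, cfg.burn_in, cfg.thin, rng_final,
                        inits=inits, gamma_scope=gamma_scope)
    n_iter_used = cfg.n_iter
    escalated = False
    means, quants, rhat, ess = _summaries(draws, names)
    if max(rhat.values()) > cfg.rhat_threshold and cfg.escalation_iter > cfg.n_iter:
        escalated = True
        draws = _run_chains(name, y, nobs, d_proto, d_ex, lo, hi, cfg.n_chains,
                            cfg.escalation_iter, cfg.burn_in, cfg.thin, rng_esc,
                            inits=inits, gamma_scope=gamma_scope)
        n_iter_used = cfg.escalation_iter
        means, quants, rhat, ess = _summaries(draws, names)
    converged = max(rhat.values()) <= cfg.rhat_threshold

    dic = compute_dic(name, data, distances, draws, gamma_scope=gamma_scope)
    return FitResult(model=name, draws=draws, param_names=names,
                     posterior_mean=means, quantiles=quants, rhat=rhat, ess=ess,
                     dic=dic, converged=converged, escalated=escalated,
                     n_iter_used=n_iter_used, init_values=inits, seed=seed)


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionReport:
    """DIC ranking of a subject's fitted models against guessing."""

    ranking: list[tuple[str, float]]  # (model, DIC), ascending, converged only
    best_model: str
    guessing_dic: float
    guess_level: bool
    excluded: list[str]  # non-converged models
    delta_guess: float


def select_model(fits: list[FitResult], guessing_fit: FitResult,
                 delta_guess: float = 2.0, tie_epsilon: float = 0.5) -> SelectionReport:
    """Rank converged fits by DIC (ascending).

    Near-ties (|delta DIC| < ``tie_epsilon``) are broken toward fewer free
    parameters.  The subject is flagged guess-level when the best model's
    DIC is not at least ``delta_guess`` below the guessing DIC.
    """
    if guessing_fit.model != "GUESS":
        raise SelectionError("guessing_fit must be the GUESS model")
    converged = [f for f in fits if f.converged and f.model != "GUESS"]
    excluded = [f.model for f in fits if not f.converged]
    if not converged:
        raise SelectionError("no converged fits to rank")

    def sort_key(f: FitResult):
        return (f.dic.dic, len(f.param_names))

    ordered = sorted(converged, key=sort_key)
    # stable tie-break: within tie_epsilon of the current best, prefer fewer params
    best = ordered[0]
    for f in ordered[1:]:
        if abs(f.dic.dic - best.dic.dic) < tie_epsilon and len(f.param_names) < len(best.param_names):
            best = f
    guess_dic = guessing_fit.dic.dic
    return SelectionReport(
        ranking=[(f.model, f.dic.dic) for f in ordered],
        best_model=best.model,
        guessing_dic=guess_dic,
        guess_level=not (best.dic.dic <= guess_dic - delta_guess),
        excluded=excluded,
        delta_guess=delta_guess,
    )
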