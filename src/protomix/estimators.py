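"""scikit-learn style estimator over the Bayesian observation-model fits.

The feature matrix is the item-distance geometry: column 0 is the distance
to the prototype and the remaining columns are distances to the training
exemplars.  The target is the per-item endorsement count (or binary
response); ``n_trials`` gives the binomial denominator.  This makes a fit
composable with sklearn's ``clone``/pipelines while the heavy lifting stays
in :mod:`protomix.inference`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DataError
from .inference import ChainConfig, PriorSpec, fit_model
from .models import EndorsementData, ItemDistances


class BayesianEndorsementModel(BaseEstimator):
    """Per-subject Bayesian fit of one observation-model variant.

    Parameters
    ----------
    model : one of PROTO, EX, EX_G, MIX, MIX_2C, MIX_G, MIX_2C_G, GUESS.
    n_trials : binomial denominator per item (1 = binary training data,
        8 = the usual transfer aggregate).
    n_chains, n_iter, burn_in, thin, escalation_iter, rhat_threshold :
        chain schedule, see :class:`protomix.inference.ChainConfig`.
    gamma_scope : whether response scaling applies to "both" mixture
        components or the "exemplar_only" one.
    seed : MCMC seed.

    Attributes (after fit)
    ----------------------
    result_ : the full :class:`protomix.inference.FitResult`.
    posterior_mean_ : dict of posterior means per free parameter.
    rhat_ : dict of split-chain Rhat per parameter.
    dic_ : DIC of the fit.
    converged_ : whether all Rhat values met the threshold.
    """

    def __init__(self, model: str = "MIX", n_trials: int = 1, n_chains: int = 4,
                 n_iter: int = 5000, burn_in: int = 1000, thin: int = 5,
                 init_n_iter: int = 2000, init_burn_in: int = 500,
                 escalation_iter: int = 20000, rhat_threshold: float = 1.1,
                 gamma_scope: str = "both", seed: int = 0):
        self.model = model
        self.n_trials = n_trials
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.init_n_iter = init_n_iter
        self.init_burn_in = init_burn_in
        self.escalation_iter = escalation_iter
        self.rhat_threshold = rhat_threshold
        self.gamma_scope = gamma_scope
        self.seed = seed

    def _chain_config(self) -> ChainConfig:
        return ChainConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                           burn_in=self.burn_in, thin=self.thin,
                           init_n_iter=self.init_n_iter,
                           init_burn_in=self.init_burn_in,
                           escalation_iter=self.escalation_iter,
                           rhat_threshold=self.rhat_threshold)

    def _geometry(self, X) -> ItemDistances:
        X = check_array(X, ensure_min_features=2)
        if np.any(X < 0):
            raise DataError("distances must be non-negative")
        ids = np.array([f"item{i:03d}" for i in range(X.shape[0])], dtype=object)
        return ItemDistances(item_ids=ids, d_proto=X[:, 0], d_ex=X[:, 1:])

    def fit(self, X, y):
        """Fit the model to endorsement counts.

        X : (n_items, 1 + n_exemplars) distance matrix.
        y : (n_items,) endorsement counts in [0, n_trials].
        """
        geom = self._geometry(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != len(geom.item_ids):
            raise DataError("X and y must have the same number of items")
        data = EndorsementData.from_counts(
            geom.item_ids, y, np.full(y.shape[0], float(self.n_trials)),
            phase="transfer" if self.n_trials > 1 else "training")
        self.result_ = fit_model(self.model, data, geom, priors=PriorSpec(),
                                 chains=self._chain_config(), seed=self.seed,
                                 gamma_scope=self.gamma_scope)
        self.posterior_mean_ = self.result_.posterior_mean
        self.rhat_ = self.result_.rhat
        self.dic_ = self.result_.dic.dic
        self.converged_ = self.result_.converged
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0]) + 1
        return self

    def predict_proba(self, X):
        """Posterior-mean endorsement probabilities, as (n, 2) columns
        [P(not endorse), P(endorse)]."""
        check_is_fitted(self, "result_")
        geom = self._geometry(X)
        from .models import predict_endorsement

        if self.model == "GUESS":
            r = np.full(len(geom.item_ids), 0.5)
        else:
            r = predict_endorsement(self.model, self.result_.posterior_parameters,
                                    geom.d_proto, geom.d_ex,
                                    gamma_scope=self.gamma_scope)
        return np.column_stack([1.0 - r, r])

    def predict(self, X):
        """Most likely response per item (endorse = 1)."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean per-trial Bernoulli log-likelihood at the posterior means."""
        r = np.clip(self.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        y = np.asarray(y, dtype=float).ravel()
        n = float(self.n_trials)
        ll = y * np.log(r) + (n - y) * np.log1p(-r)
        return float(ll.sum() / (n * len(y)))
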