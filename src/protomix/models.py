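"""Observation models for single-category endorsement decisions.

Similarity of an item to the category decays exponentially with distance,
``s = exp(-c * d)``, with sensitivity ``c`` controlling the steepness of the
generalization gradient.  The prototype model measures similarity to the
prototype alone; the exemplar model sums similarity over the training
exemplars.  Endorsement probabilities follow a Luce-style rule
``r = s / (s + k)`` with criterion ``k`` (larger ``k`` = stricter policy);
mixture models blend the prototype and exemplar rules with weight ``beta``,
and gamma-variants raise similarity and criterion to a response-scaling
exponent ``gamma`` that makes choices more (>1) or less (<1) deterministic.
A guessing model fixes every endorsement probability at 0.5.

Model variants
--------------
========  ==========================  =====================================
name      free parameters             endorsement rule
========  ==========================  =====================================
PROTO     c, k                        s_p/(s_p+k)
EX        c, k                        s_e/(s_e+k)
EX_G      c, k, gamma                 s_e^g/(s_e^g+k^g)
MIX       c, k, beta                  b*r_proto + (1-b)*r_ex
MIX_2C    c_proto, c_ex, k, beta      as MIX with per-process sensitivities
MIX_G     c, k, beta, gamma           as MIX with gamma-scaled components
MIX_2C_G  c_proto, c_ex, k, b, gamma  as MIX_2C with gamma scaling
GUESS     (none)                      0.5 everywhere
========  ==========================  =====================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, UndefinedCorrelationError
from . import stimuli as _stim

MODEL_NAMES = ("PROTO", "EX", "EX_G", "MIX", "MIX_2C", "MIX_G", "MIX_2C_G", "GUESS")

MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "PROTO": ("c", "k"),
    "EX": ("c", "k"),
    "EX_G": ("c", "k", "gamma"),
    "MIX": ("c", "k", "beta"),
    "MIX_2C": ("c_proto", "c_ex", "k", "beta"),
    "MIX_G": ("c", "k", "beta", "gamma"),
    "MIX_2C_G": ("c_proto", "c_ex", "k", "beta", "gamma"),
    "GUESS": (),
}

_MIXTURE_MODELS = frozenset({"MIX", "MIX_2C", "MIX_G", "MIX_2C_G"})
_GAMMA_MODELS = frozenset({"EX_G", "MIX_G", "MIX_2C_G"})
_TWO_C_MODELS = frozenset({"MIX_2C", "MIX_2C_G"})

#: probability floor used inside log-likelihoods only, never in reported r
_P_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """A model variant and its free-parameter list."""

    name: str

    def __post_init__(self):
        if self.name not in MODEL_FREE_PARAMS:
            raise ConfigurationError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return MODEL_FREE_PARAMS[self.name]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    @property
    def is_mixture(self) -> bool:
        return self.name in _MIXTURE_MODELS

    @property
    def has_gamma(self) -> bool:
        return self.name in _GAMMA_MODELS


def _model_name(model) -> str:
    return model.name if isinstance(model, ModelSpec) else str(model)


@dataclass
class ParameterSet:
    """Free parameters of one model variant.

    Only the fields named by the model's spec are meaningful; ``gamma``
    defaults to 1 when absent.  Bounds: c, c_proto, c_ex >= 0; k in (0, 1];
    beta in [0, 1]; gamma > 0.
    """

    c: float | None = None
    c_proto: float | None = None
    c_ex: float | None = None
    k: float | None = None
    beta: float | None = None
    gamma: float | None = None

    def validate(self, model) -> None:
        name = _model_name(model)
        for p in MODEL_FREE_PARAMS[name]:
            v = getattr(self, p)
            if v is None:
                raise ConfigurationError(f"model {name} requires parameter {p!r}")
            if p in ("c", "c_proto", "c_ex") and v < 0:
                raise ConfigurationError(f"{p} must be >= 0, got {v}")
            if p == "k" and not (0 < v <= 1):
                raise ConfigurationError(f"k must lie in (0, 1], got {v}")
            if p == "beta" and not (0 <= v <= 1):
                raise ConfigurationError(f"beta must lie in [0, 1], got {v}")
            if p == "gamma" and not (v > 0):
                raise ConfigurationError(f"gamma must be > 0, got {v}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def to_theta(self, model) -> np.ndarray:
        """Pack the model's free parameters into a vector (spec order)."""
        self.validate(model)
        return np.array([getattr(self, p) for p in MODEL_FREE_PARAMS[_model_name(model)]],
                        dtype=float)

    @classmethod
    def from_theta(cls, model, theta) -> "ParameterSet":
        names = MODEL_FREE_PARAMS[_model_name(model)]
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(names),):
            raise ConfigurationError(f"theta shape {theta.shape} != ({len(names)},)")
        return cls(**dict(zip(names, theta)))


# ---------------------------------------------------------------------------
# similarity primitives


def similarity_to_prototype(d, c):
    """exp(-c*d): similarity of an item at prototype distance ``d``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(np.asarray(c) < 0):
        raise ConfigurationError("distance and sensitivity must be non-negative")
    return np.exp(-np.multiply(c, d))


def similarity_to_exemplars(d_vec, c):
    """Summed exemplar similarity: sum_j exp(-c*d_ij) over the last axis.

    ``d_vec`` holds the distances of one item (or of many items, rows) to
    every training exemplar.  A training item evaluated against a set that
    contains itself contributes exactly 1 through its self term.
    """
    d_vec = np.asarray(d_vec, dtype=float)
    if d_vec.size == 0 or d_vec.shape[-1] == 0:
        raise ConfigurationError("empty exemplar set")
    if np.any(d_vec < 0) or np.any(np.asarray(c) < 0):
        raise ConfigurationError("distance and sensitivity must be non-negative")
    return np.exp(-np.multiply(c, d_vec)).sum(axis=-1)


def _luce(s, k, gamma=None):
    if gamma is None:
        return s / (s + k)
    sg = np.power(s, gamma)
    return sg / (sg + np.power(k, gamma))


def endorsement_probability(model, params: ParameterSet, s_proto=None, s_ex=None,
                            gamma_scope: str = "both"):
    """Endorsement probability from precomputed similarities.

    For the two-sensitivity variants the caller must supply ``s_proto``
    computed with ``c_proto`` and ``s_ex`` with ``c_ex``.  ``gamma_scope``
    chooses whether gamma scaling applies to both mixture components or to
    the exemplar component only.
    """
    name = _model_name(model)
    if name == "GUESS":
        ref = s_proto if s_proto is not None else s_ex
        shape = np.shape(ref) if ref is not None else ()
        return np.full(shape, 0.5) if shape else 0.5
    params.validate(name)
    if gamma_scope not in ("both", "exemplar_only"):
        raise ConfigurationError(f"gamma_scope {gamma_scope!r}")
    k = params.k
    g = params.gamma if name in _GAMMA_MODELS else None
    g_proto = g if (g is not None and gamma_scope == "both") else None
    if name == "PROTO":
        return _luce(np.asarray(s_proto, dtype=float), k)
    if name in ("EX", "EX_G"):
        return _luce(np.asarray(s_ex, dtype=float), k, g)
    # mixture family
    r_p = _luce(np.asarray(s_proto, dtype=float), k, g_proto)
    r_e = _luce(np.asarray(s_ex, dtype=float), k, g)
    return params.beta * r_p + (1.0 - params.beta) * r_e


def predict_endorsement_theta(model, theta, d_proto, d_ex, gamma_scope: str = "both"):
    """Vectorised endorsement probabilities.

    theta : (..., p) array in the model's free-parameter order.
    d_proto : (n_items,) prototype distances.
    d_ex : (n_items, n_exemplars) exemplar distances.
    Returns r with shape (..., n_items).
    """
    name = _model_name(model)
    d_proto = np.asarray(d_proto, dtype=float)
    d_ex = np.asarray(d_ex, dtype=float)
    if name == "GUESS":
        return np.full(d_proto.shape, 0.5)
    theta = np.asarray(theta, dtype=float)
    names = MODEL_FREE_PARAMS[name]
    f = {p: theta[..., i][..., None] for i, p in enumerate(names)}  # (..., 1)
    k = f["k"]
    g = f["gamma"] if name in _GAMMA_MODELS else None
    g_proto = g if (g is not None and gamma_scope == "both") else None

    c_ex = f["c_ex"] if name in _TWO_C_MODELS else f.get("c")
    s_e = None
    if name != "PROTO":
        s_e = np.exp(-c_ex[..., None] * d_ex).sum(axis=-1)
    if name in ("EX", "EX_G"):
        return _luce(s_e, k, g)
    c_p = f["c_proto"] if name in _TWO_C_MODELS else f["c"]
    s_p = np.exp(-c_p * d_proto)
    if name == "PROTO":
        return _luce(s_p, k)
    r_p = _luce(s_p, k, g_proto)
    r_e = _luce(s_e, k, g)
    b = f["beta"]
    return b * r_p + (1.0 - b) * r_e


def predict_endorsement(model, params: ParameterSet, d_proto, d_ex,
                        gamma_scope: str = "both"):
    """Endorsement probabilities of items given distances (ParameterSet API)."""
    name = _model_name(model)
    if name == "GUESS":
        return np.full(np.asarray(d_proto, dtype=float).shape, 0.5)
    return predict_endorsement_theta(name, params.to_theta(name), d_proto, d_ex,
                                     gamma_scope=gamma_scope)


# ---------------------------------------------------------------------------
# endorsement data


@dataclass(eq=False)
class EndorsementData:
    """Per-item endorsement observations.

    Training rounds yield one binary response per item (``n_obs`` = 1,
    ``endorsed`` in {0, 1}); timeouts are recorded as ``n_obs`` = 0 and drop
    out of the likelihood.  Transfer data aggregate endorsement counts over
    the rounds in which the item was observed.
    """

    phase: str
    item_ids: np.ndarray
    endorsed: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        self.item_ids = np.asarray(self.item_ids, dtype=object)
        self.endorsed = np.asarray(self.endorsed, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=float)
        if self.phase not in ("training", "transfer"):
            raise DataError(f"phase {self.phase!r}")
        if not (len(self.item_ids) == len(self.endorsed) == len(self.n_obs)):
            raise DataError("item_ids, endorsed and n_obs must be equally long")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise DataError("duplicated item ids")
        if np.any(self.endorsed < 0) or np.any(self.endorsed > self.n_obs):
            raise DataError("endorsement counts must lie in [0, n_obs]")

    @property
    def n_trials(self) -> float:
        """Total observed trial count (timeouts excluded)."""
        return float(self.n_obs.sum())

    @classmethod
    def from_binary(cls, item_ids, responses, phase: str = "training") -> "EndorsementData":
        """One round of binary responses; NaN marks a timeout."""
        responses = np.asarray(responses, dtype=float)
        ok = ~np.isnan(responses)
        return cls(phase=phase, item_ids=np.asarray(item_ids, dtype=object),
                   endorsed=np.where(ok, responses, 0.0),
                   n_obs=ok.astype(float))

    @classmethod
    def from_counts(cls, item_ids, endorsed, n_obs, phase: str = "transfer") -> "EndorsementData":
        return cls(phase=phase, item_ids=item_ids, endorsed=endorsed, n_obs=n_obs)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, phase: str,
                    round_index: int | None = None) -> "EndorsementData":
        """Aggregate a tidy trial table (columns item_id, round, response).

        Training: pass ``round_index`` to select one round's binary vector.
        Transfer: responses are counted over all rounds per item.
        """
        sub = trials[trials["phase"] == phase]
        if phase == "training":
            if round_index is None:
                raise DataError("training data are fitted per round; pass round_index")
            sub = sub[sub["round"] == round_index]
            if sub.empty:
                raise DataError(f"no training trials in round {round_index}")
            return cls.from_binary(sub["item_id"].to_numpy(), sub["response"].to_numpy())
        if sub.empty:
            raise DataError("no transfer trials")
        grp = sub.groupby("item_id", sort=False)["response"]
        return cls.from_counts(grp.sum(min_count=1).fillna(0.0).index.to_numpy(),
                               grp.sum(min_count=1).fillna(0.0).to_numpy(),
                               grp.count().to_numpy(), phase="transfer")


@dataclass
class ItemDistances:
    """Prototype and exemplar distances of a fixed item list.

    The likelihood context: ``d_proto[i]`` is item i's distance to the
    prototype, ``d_ex[i, j]`` its distance to training exemplar j.
    """

    item_ids: np.ndarray
    d_proto: np.ndarray
    d_ex: np.ndarray

    def __post_init__(self):
        self.item_ids = np.asarray(self.item_ids, dtype=object)
        self.d_proto = np.asarray(self.d_proto, dtype=float)
        self.d_ex = np.asarray(self.d_ex, dtype=float)
        if self.d_proto.shape[0] != len(self.item_ids) or self.d_ex.shape[0] != len(self.item_ids):
            raise ConfigurationError("distance arrays must align with item_ids")

    @classmethod
    def from_stimulus_set(cls, sset: "_stim.StimulusSet", items: str = "transfer") -> "ItemDistances":
        """Build the context for the training (24-item) or transfer (41-item)
        set; exemplars are always the 12 training members."""
        if items == "transfer":
            pats = sset.transfer_items()
        elif items == "training":
            pats = sset.training_items()
        else:
            raise ConfigurationError(f"items must be 'training' or 'transfer', got {items!r}")
        exemplars = sset.training_members
        d_proto = np.array([_stim.pattern_distance(p, sset.prototype) for p in pats])
        d_ex = np.array([[_stim.pattern_distance(p, e) for e in exemplars] for p in pats])
        return cls(item_ids=np.array([p.id for p in pats], dtype=object),
                   d_proto=d_proto, d_ex=d_ex)

    def align(self, data: EndorsementData) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Reorder distances to the data's item order.

        Returns (d_proto, d_ex, endorsed, n_obs); raises on unknown items.
        """
        index = {pid: i for i, pid in enumerate(self.item_ids)}
        try:
            rows = np.array([index[pid] for pid in data.item_ids])
        except KeyError as exc:
            raise DataError(f"item {exc.args[0]!r} absent from distance table") from exc
        return self.d_proto[rows], self.d_ex[rows], data.endorsed, data.n_obs


def log_likelihood(model, params: ParameterSet | None, data: EndorsementData,
                   distances: ItemDistances, gamma_scope: str = "both") -> float:
    """Bernoulli/Binomial log-likelihood of endorsement data.

    Training data are Bernoulli per binary response; transfer counts are
    Binomial over the per-item round denominator, written in product-Bernoulli
    form (no combinatorial constant, which cancels in model comparison).
    Probabilities are clipped to [1e-12, 1-1e-12] here only.
    """
    d_proto, d_ex, y, n = distances.align(data)
    r = predict_endorsement(model, params, d_proto, d_ex, gamma_scope=gamma_scope)
    r = np.clip(r, _P_FLOOR, 1.0 - _P_FLOOR)
    return float(np.sum(y * np.log(r) + (n - y) * np.log1p(-r)))


def log_likelihood_theta(model, theta, y, n_obs, d_proto, d_ex,
                         gamma_scope: str = "both") -> np.ndarray:
    """Likelihood over packed parameter vectors; theta (..., p) -> (...,)."""
    r = predict_endorsement_theta(model, theta, d_proto, d_ex, gamma_scope=gamma_scope)
    r = np.clip(r, _P_FLOOR, 1.0 - _P_FLOOR)
    return (y * np.log(r) + (n_obs - y) * np.log1p(-r)).sum(axis=-1)


# ---------------------------------------------------------------------------
# similarity vectors


@dataclass(eq=False)
class SimilarityVector:
    """Per-item prototype, exemplar and beta-weighted similarities."""

    item_ids: np.ndarray
    s_proto: np.ndarray
    s_ex: np.ndarray
    s_mix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "s_proto": self.s_proto,
                             "s_ex": self.s_ex, "s_mix": self.s_mix})


def mixture_similarity_vector(s_proto_vec, s_ex_vec, beta: float,
                              item_ids=None) -> SimilarityVector:
    """Blend prototype and exemplar similarity into a single vector:
    s_mix = beta*s_proto + (1-beta)*s_ex."""
    s_p = np.asarray(s_proto_vec, dtype=float)
    s_e = np.asarray(s_ex_vec, dtype=float)
    if s_p.shape != s_e.shape:
        raise ConfigurationError(f"length mismatch: {s_p.shape} vs {s_e.shape}")
    if not (0 <= beta <= 1):
        raise ConfigurationError(f"beta must lie in [0, 1], got {beta}")
    if item_ids is None:
        item_ids = np.arange(len(s_p))
    return SimilarityVector(item_ids=np.asarray(item_ids, dtype=object),
                            s_proto=s_p, s_ex=s_e,
                            s_mix=beta * s_p + (1.0 - beta) * s_e)


def similarity_correlation(s_proto_vec, s_ex_vec, item_subset=None) -> float:
    """Pearson correlation of prototype vs exemplar similarity over a subset.

    Used to judge whether the two vectors are identifiable as separate
    predictors; raises if either vector has zero variance.
    """
    s_p = np.asarray(s_proto_vec, dtype=float)
    s_e = np.asarray(s_ex_vec, dtype=float)
    if item_subset is not None:
        item_subset = np.asarray(item_subset)
        s_p, s_e = s_p[item_subset], s_e[item_subset]
    if len(s_p) < 3:
        raise ConfigurationError("need at least 3 items for a correlation")
    if np.std(s_p) == 0 or np.std(s_e) == 0:
        raise UndefinedCorrelationError("zero variance in a similarity vector")
    return float(np.corrcoef(s_p, s_e)[0, 1])
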