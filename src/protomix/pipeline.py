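"""End-to-end orchestration: training protocol, accuracy summaries,
participant QC, recovery experiments, similarity-vector export and
reporting."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, QCError, StateError
from .inference import FAST_CHAINS, ChainConfig, FitResult, fit_model, select_model
from .models import (
    EndorsementData,
    ItemDistances,
    MODEL_FREE_PARAMS,
    mixture_similarity_vector,
    similarity_to_exemplars,
    similarity_to_prototype,
)
from .stimuli import StimulusSet, read_stimuli
from . import synthetic_data as synth

MAX_ROUNDS = 14
MIN_ROUNDS = 8
CRITERION = 0.75
ROUNDS_AT_CRITERION = 4


# ---------------------------------------------------------------------------
# training protocol engine


@dataclass(frozen=True)
class ProtocolState:
    """State of the adaptive training schedule.

    Training ends once at least 8 rounds are done and at least 4 of them
    reached 75% accuracy, or after 14 rounds regardless.
    """

    round_index: int = 0
    accuracy_history: tuple[float, ...] = ()
    rounds_at_criterion: int = 0
    terminated: bool = False
    termination_reason: str | None = None


def advance_protocol(state: ProtocolState, round_accuracy: float,
                     min_rounds: int = MIN_ROUNDS, max_rounds: int = MAX_ROUNDS,
                     criterion: float = CRITERION,
                     rounds_at_criterion_required: int = ROUNDS_AT_CRITERION) -> ProtocolState:
    """Record one finished round and evaluate the stop rule."""
    if state.terminated:
        raise StateError("cannot advance a terminated protocol")
    if not (0.0 <= round_accuracy <= 1.0):
        raise ConfigurationError(f"round accuracy {round_accuracy} outside [0, 1]")
    rounds = state.round_index + 1
    at_crit = state.rounds_at_criterion + (1 if round_accuracy >= criterion else 0)
    terminated, reason = False, None
    if rounds >= min_rounds and at_crit >= rounds_at_criterion_required:
        terminated, reason = True, "criterion"
    elif rounds >= max_rounds:
        terminated, reason = True, "round_cap"
    return ProtocolState(round_index=rounds,
                         accuracy_history=state.accuracy_history + (float(round_accuracy),),
                         rounds_at_criterion=at_crit,
                         terminated=terminated, termination_reason=reason)


# ---------------------------------------------------------------------------
# accuracy summaries

_GROUPING_COLUMNS = {
    "membership": "membership",
    "round": "round",
    "dl": "dl",
    "group": "group",
    "novelty": "novelty",
    "subject": "subject_id",
    "phase": "phase",
}


def accuracy_summary(dataset, grouping=("group", "membership")) -> pd.DataFrame:
    """Mean accuracy per grouping cell; timeouts are excluded from the
    denominators.  Distortion-level summaries are restricted to members and
    novelty contrasts to DL5-7 members (the levels present in both the
    training and the novel transfer items)."""
    trials = dataset.trials if hasattr(dataset, "trials") else dataset
    if trials.empty:
        raise DataError("empty dataset")
    df = trials.copy()
    df["membership"] = np.where(df["role"].isin(["member", "prototype"]),
                                "member", "nonmember")
    grouping = list(grouping)
    unknown = [g for g in grouping if g not in _GROUPING_COLUMNS]
    if unknown:
        raise ConfigurationError(f"unknown grouping keys {unknown}")
    if "dl" in grouping or "novelty" in grouping:
        df = df[df["role"] == "member"]
    if "novelty" in grouping:
        df = df[df["dl"].isin([5, 6, 7])]
    cols = [_GROUPING_COLUMNS[g] for g in grouping]
    out = (df.groupby(cols, dropna=False)["correct"]
           .agg(accuracy="mean", n_trials="count").reset_index())
    if out["accuracy"].isna().any() or (out["n_trials"] == 0).any():
        warnings.warn("empty cells in accuracy summary (all-timeout groups)")
    return out


# ---------------------------------------------------------------------------
# participant QC


@dataclass
class QCReport:
    subject_id: str
    low_performance: bool
    guess_level: bool
    trait_outlier: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def included(self) -> bool:
        return not (self.low_performance or self.guess_level or self.trait_outlier)


def participant_qc(dataset, selections: dict, trait_scores: dict | pd.Series,
                   accuracy_threshold: float = 0.75, trait_cutoff: float = 32.0,
                   sd_multiplier: float = 3.0) -> pd.DataFrame:
    """Apply the three exclusion filters per subject.

    low_performance: accuracy below threshold in BOTH the last completed
    training round and the transfer phase average.  guess_level: taken from
    the model-selection report.  trait_outlier: trait score above the
    clinical cutoff or more than ``sd_multiplier`` SDs above the cohort mean.
    """
    trials = dataset.trials if hasattr(dataset, "trials") else dataset
    scores = pd.Series(trait_scores, dtype=float)
    mean, sd = scores.mean(), scores.std(ddof=1)
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        train = sub[sub["phase"] == "training"]
        transfer = sub[sub["phase"] == "transfer"]
        if train.empty or transfer.empty:
            raise QCError(f"subject {sid}: missing a phase")
        last_round = train["round"].max()
        acc_last = train.loc[train["round"] == last_round, "correct"].mean()
        acc_transfer = transfer["correct"].mean()
        low_perf = bool(acc_last < accuracy_threshold and acc_transfer < accuracy_threshold)
        if sid not in selections:
            raise QCError(f"subject {sid}: no model-selection (guessing) report")
        guess = bool(selections[sid].guess_level)
        score = float(scores[sid])
        outlier = bool(score > trait_cutoff or (sd > 0 and score > mean + sd_multiplier * sd))
        reasons = [r for r, f in
                   [("low_performance", low_perf), ("guess_level", guess),
                    ("trait_outlier", outlier)] if f]
        rows.append({"subject_id": sid, "low_performance": low_perf,
                     "guess_level": guess, "trait_outlier": outlier,
                     "included": not reasons, "reasons": ";".join(reasons),
                     "last_training_accuracy": float(acc_last),
                     "transfer_accuracy": float(acc_transfer),
                     "trait_score": score})
    return pd.DataFrame(rows)


def median_split(trait_scores: dict | pd.Series) -> pd.Series:
    """Utility parity with trait-based grouping of real cohorts: label
    subjects above the median high, the rest low."""
    scores = pd.Series(trait_scores, dtype=float)
    med = scores.median()
    return pd.Series(np.where(scores > med, "AQ_high", "AQ_low"), index=scores.index)


# ---------------------------------------------------------------------------
# recovery experiments


@dataclass
class RecoveryReport:
    """Parameter-recovery table and model-recovery confusion matrix."""

    parameters: pd.DataFrame  # entry, param, truth, post_mean, ci_low, ci_high, covered
    confusion: pd.DataFrame | None
    errors: list[str] = field(default_factory=list)

    def coverage(self) -> float:
        return float(self.parameters["covered"].mean())

    def bias(self) -> pd.Series:
        d = self.parameters
        return (d["post_mean"] - d["truth"]).groupby(d["param"]).mean()

    def rmse(self) -> pd.Series:
        d = self.parameters
        err2 = (d["post_mean"] - d["truth"]) ** 2
        return np.sqrt(err2.groupby(d["param"]).mean())


def run_recovery(suite: synth.RecoverySuite, fit_models=None,
                 chains: ChainConfig | None = None, seed: int = 0) -> RecoveryReport:
    """Fit every labelled dataset of a recovery suite.

    The generating model is always fitted (parameter recovery); when
    ``fit_models`` lists several models, each dataset is additionally ranked
    across them by DIC and a confusion matrix is accumulated.
    """
    chains = chains or FAST_CHAINS
    dists = ItemDistances.from_stimulus_set(suite.stimuli, "transfer")
    fit_models = list(fit_models or [suite.model])
    if suite.model not in fit_models:
        fit_models = [suite.model] + fit_models
    ss = np.random.SeedSequence(seed)
    fit_seeds = iter(int(s.generate_state(1)[0] % (2**31))
                     for s in ss.spawn(len(suite.entries) * len(fit_models)))

    rows, conf_rows, errors = [], [], []
    for e_idx, entry in enumerate(suite.entries):
        dics = {}
        for m in fit_models:
            s = next(fit_seeds)
            try:
                fit = fit_model(m, entry.data, dists, chains=chains, seed=s)
            except Exception as exc:  # recorded, not fatal
                errors.append(f"entry {e_idx} model {m}: {exc}")
                continue
            dics[m] = fit.dic.dic
            if m == suite.model:
                for p in fit.param_names:
                    truth = getattr(entry.true_params, p)
                    lo, hi = fit.quantiles[p][2.5], fit.quantiles[p][97.5]
                    rows.append({"entry": e_idx, "param": p, "truth": truth,
                                 "post_mean": fit.posterior_mean[p],
                                 "ci_low": lo, "ci_high": hi,
                                 "covered": bool(lo <= truth <= hi),
                                 "converged": fit.converged})
        if len(dics) > 1:
            conf_rows.append({"true_model": suite.model,
                              "selected_model": min(dics, key=dics.get)})

    confusion = None
    if conf_rows:
        cdf = pd.DataFrame(conf_rows)
        confusion = pd.crosstab(cdf["true_model"], cdf["selected_model"])
    return RecoveryReport(parameters=pd.DataFrame(rows), confusion=confusion,
                          errors=errors)


# ---------------------------------------------------------------------------
# similarity-vector export


def export_similarity_vectors(fit: FitResult, sset: StimulusSet, trials: pd.DataFrame,
                              phase: str = "training") -> pd.DataFrame:
    """Per correctly-categorized member trial: s_proto and s_ex at the
    posterior-mean parameters, plus the beta-weighted s_mix for mixture
    fits.  These are the parametric-modulator vectors of downstream neural
    analyses.  Refuses non-converged fits."""
    if not fit.converged:
        raise DataError(f"fit of {fit.model} did not converge; refusing export")
    params = fit.posterior_parameters
    names = MODEL_FREE_PARAMS[fit.model]
    c_p = params.c_proto if "c_proto" in names else params.c
    c_e = params.c_ex if "c_ex" in names else params.c
    dists = ItemDistances.from_stimulus_set(
        sset, "transfer" if phase == "transfer" else "training")
    sub = trials[(trials["phase"] == phase)
                 & (trials["role"].isin(["member", "prototype"]))
                 & (trials["correct"] == 1)]
    index = {pid: i for i, pid in enumerate(dists.item_ids)}
    rows = np.array([index[pid] for pid in sub["item_id"]], dtype=int)
    s_p = similarity_to_prototype(dists.d_proto[rows], c_p)
    s_e = similarity_to_exemplars(dists.d_ex[rows], c_e) if len(rows) else np.array([])
    out = sub[["subject_id", "phase", "round", "item_id"]].copy() \
        if "subject_id" in sub.columns else sub[["phase", "round", "item_id"]].copy()
    out["s_proto"] = s_p
    out["s_ex"] = s_e
    if params.beta is not None:
        out["s_mix"] = mixture_similarity_vector(s_p, s_e, params.beta).s_mix
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# demo run + report

DEMO_MODELS = ("MIX", "PROTO", "EX", "GUESS")


def run_demo(out_dir, seed: int = 0, n_per_group: int = 2,
             chains: ChainConfig | None = None) -> Path:
    """Small end-to-end run (generate -> simulate -> fit -> QC -> recovery)
    whose artifacts feed :func:`report`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chains = chains or FAST_CHAINS
    cohort = synth.simulate_cohort(synth.CohortConfig(n_per_group=n_per_group, seed=seed))
    cohort.write(out)
    dists = ItemDistances.from_stimulus_set(cohort.stimuli, "transfer")

    ss = np.random.SeedSequence(seed + 1)
    seeds = iter(int(s.generate_state(1)[0] % (2**31))
                 for s in ss.spawn(len(cohort.agents) * len(DEMO_MODELS)))
    fit_rows, selections = [], {}
    for sid in cohort.agents["subject_id"]:
        data = EndorsementData.from_trials(cohort.trials[cohort.trials["subject_id"] == sid],
                                           "transfer")
        fits = []
        for m in DEMO_MODELS:
            fit = fit_model(m, data, dists, chains=chains, seed=next(seeds))
            fits.append(fit)
            row = {"subject_id": sid, "model": m, "dic": fit.dic.dic,
                   "p_d": fit.dic.p_d, "converged": fit.converged}
            row.update({f"mean_{p}": v for p, v in fit.posterior_mean.items()})
            fit_rows.append(row)
        guess = next(f for f in fits if f.model == "GUESS")
        selections[sid] = select_model([f for f in fits if f.model != "GUESS"], guess)
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)

    trait = cohort.agents.set_index("subject_id")["trait_score"]
    qc = participant_qc(cohort, selections, trait)
    qc.to_csv(out / "qc.csv", index=False)

    suite = synth.make_recovery_suite(
        "MIX", {"c": [1.5], "k": [0.3], "beta": [0.2, 0.8]}, n_datasets=1, seed=seed + 2)
    rec = run_recovery(suite, chains=chains, seed=seed + 3)
    rec.parameters.to_csv(out / "recovery.csv", index=False)
    report(out)
    return out / "report.md"


def report(run_dir) -> str:
    """Assemble a markdown summary of a run directory and write report.md.

    Sections: stimulus constraints, QC table, DIC table, parameter
    trajectories, recovery metrics.  Missing artifacts yield warnings, an
    empty directory is an error.
    """
    run = Path(run_dir)
    if not run.is_dir() or not any(run.iterdir()):
        raise DataError(f"{run} is not a completed run directory")
    lines = ["# protomix run report", ""]

    lines.append("## Stimulus constraints")
    stim_path = run / "stimuli.json"
    if stim_path.exists():
        sset = read_stimuli(stim_path)
        from .stimuli import pattern_distance

        dmem = max(pattern_distance(m, sset.prototype) for m in sset.members())
        dnon = min(pattern_distance(n, sset.prototype) for n in sset.nonmembers())
        sset.validate()
        lines += [f"- inventory: {len(sset.all_patterns())} patterns, constraints satisfied",
                  f"- max member distance to prototype: {dmem:.3f} (<= 6.22)",
                  f"- min nonmember distance to prototype: {dnon:.3f} (>= 12.93)", ""]
    else:
        lines += ["- WARNING: stimuli.json missing", ""]

    lines.append("## Participant QC")
    qc_path = run / "qc.csv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path)
        lines += [qc.to_string(index=False), ""]
    else:
        lines += ["- WARNING: qc.csv missing", ""]

    lines.append("## Model comparison (DIC)")
    fits_path = run / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        lines += [fits[["subject_id", "model", "dic", "converged"]].to_string(index=False), ""]
    else:
        lines += ["- WARNING: fits.csv missing", ""]

    lines.append("## Parameter estimates")
    if fits_path.exists():
        mean_cols = [c for c in fits.columns if c.startswith("mean_")]
        lines += [fits[["subject_id", "model"] + mean_cols].to_string(index=False), ""]
    else:
        lines += ["- WARNING: fits.csv missing", ""]

    lines.append("## Recovery metrics")
    rec_path = run / "recovery.csv"
    if rec_path.exists():
        rec = pd.read_csv(rec_path)
        cov = rec["covered"].mean()
        lines += [f"- 95% credible-interval coverage: {cov:.2f}",
                  rec.to_string(index=False), ""]
    else:
        lines += ["- WARNING: recovery.csv missing", ""]

    text = "\n".join(lines)
    (run / "report.md").write_text(text)
    return text
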