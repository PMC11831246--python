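"""Simulated cohorts of category-learning agents.

Each agent responds to stimuli according to one of the observation models,
with a per-round parameter trajectory over the training phase and a fixed
parameter set during transfer.  The default group templates emulate the
qualitative dynamics of interest: the prototype weight beta declines over
training (more slowly in the high-trait group), sensitivity c rises, the
decision criterion k loosens over training but is stricter on average in the
high-trait group.  Magnitudes are calibration constants, not claims.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .models import (
    EndorsementData,
    ItemDistances,
    MODEL_FREE_PARAMS,
    ParameterSet,
    predict_endorsement,
)
from .stimuli import GeneratorConfig, StimulusSet, build_stimulus_set

GROUPS = ("AQ_low", "AQ_high")

MAX_TRAINING_ROUNDS = 14
N_TRANSFER_ROUNDS = 8

#: prior bounds used to validate simulated parameters and recovery grids
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "c": (0.0, 5.0),
    "c_proto": (0.0, 5.0),
    "c_ex": (0.0, 5.0),
    "k": (0.0, 1.0),
    "beta": (0.0, 1.0),
    "gamma": (0.0, 20.0),
}


@dataclass
class TrajectoryTemplate:
    """(start, end) values of each parameter, interpolated linearly over the
    14 possible training rounds; transfer uses the end values."""

    beta: tuple[float, float] = (0.8, 0.2)
    c: tuple[float, float] = (0.15, 0.35)
    k: tuple[float, float] = (0.20, 0.10)
    gamma: tuple[float, float] | None = None
    model: str = "MIX"

    def params_at(self, round_index: int, n_rounds: int = MAX_TRAINING_ROUNDS) -> ParameterSet:
        """Parameters for training round ``round_index`` (1-based)."""
        w = (round_index - 1) / (n_rounds - 1)

        def interp(pair):
            return pair[0] + w * (pair[1] - pair[0])

        fields = {}
        names = MODEL_FREE_PARAMS[self.model]
        for name in names:
            if name in ("c_proto", "c_ex"):
                fields[name] = interp(self.c)
            elif name == "gamma":
                fields[name] = interp(self.gamma) if self.gamma else 1.0
            else:
                fields[name] = interp(getattr(self, name))
        ps = ParameterSet(**fields)
        ps.validate(self.model)
        return ps

    def transfer_params(self) -> ParameterSet:
        return self.params_at(MAX_TRAINING_ROUNDS)


#: default group scenario: same sensitivity growth in both groups, slower
#: beta decline and stricter criterion in the high-trait group
DEFAULT_TEMPLATES: dict[str, TrajectoryTemplate] = {
    "AQ_low": TrajectoryTemplate(beta=(0.8, 0.2), c=(0.15, 0.35), k=(0.20, 0.10)),
    "AQ_high": TrajectoryTemplate(beta=(0.8, 0.45), c=(0.15, 0.35), k=(0.30, 0.18)),
}

#: simulated trait-score (AQ-like, 0-50) distributions per group
TRAIT_SCORE_DISTS = {"AQ_low": (11.0, 4.0), "AQ_high": (23.0, 5.0)}


@dataclass
class AgentConfig:
    """One simulated participant."""

    agent_id: str
    group: str
    generating_model: str = "MIX"
    trajectory: list[ParameterSet] = field(default_factory=list)
    transfer_parameters: ParameterSet | None = None
    timeout_rate: float = 0.02

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConfigurationError(f"group {self.group!r} not in {GROUPS}")
        if not (0.0 <= self.timeout_rate <= 0.1):
            raise ConfigurationError(f"timeout_rate must lie in [0, 0.1], got {self.timeout_rate}")
        if self.trajectory and len(self.trajectory) < 8:
            raise ConfigurationError("trajectory must cover at least 8 training rounds")
        for ps in self.trajectory:
            ps.validate(self.generating_model)
        if self.transfer_parameters is not None:
            self.transfer_parameters.validate(self.generating_model)

    @classmethod
    def from_template(cls, agent_id: str, group: str, template: TrajectoryTemplate,
                      timeout_rate: float = 0.02) -> "AgentConfig":
        traj = [template.params_at(t) for t in range(1, MAX_TRAINING_ROUNDS + 1)]
        return cls(agent_id=agent_id, group=group, generating_model=template.model,
                   trajectory=traj, transfer_parameters=template.transfer_params(),
                   timeout_rate=timeout_rate)


@dataclass
class CohortConfig:
    """A reproducible simulated cohort; everything derives from the seeds."""

    n_per_group: int = 10
    stimulus_seed: int = 20
    seed: int = 0
    templates: dict[str, TrajectoryTemplate] = field(
        default_factory=lambda: {g: DEFAULT_TEMPLATES[g] for g in GROUPS}
    )
    timeout_rate: float = 0.02
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")


@dataclass
class BehaviouralDataset:
    """Tidy trials plus agent table and provenance for one simulated cohort.

    ``trials`` columns: subject_id, group, phase, round, item_id, role, dl,
    novelty, response (1/0/NaN), correct (1/0/NaN).
    """

    stimuli: StimulusSet
    trials: pd.DataFrame
    agents: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .stimuli import write_stimuli

        write_stimuli(self.stimuli, out / "stimuli.json")
        self.trials.to_csv(out / "trials.csv", index=False)
        self.agents.to_csv(out / "agents.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1, default=str))


def simulate_round(params: ParameterSet, model: str, items, distances: ItemDistances,
                   rng: np.random.Generator, timeout_rate: float = 0.0) -> pd.DataFrame:
    """Simulate one round of endorsement decisions over ``items``.

    Each item is endorsed with its model probability r; with probability
    ``timeout_rate`` the response is a timeout (NaN).  Correctness derives
    from the item's role (members and the prototype should be endorsed).
    """
    ids = [p.id for p in items]
    index = {pid: i for i, pid in enumerate(distances.item_ids)}
    try:
        rows = np.array([index[pid] for pid in ids])
    except KeyError as exc:
        raise DataError(f"item {exc.args[0]!r} missing from distance table") from exc
    r = predict_endorsement(model, params, distances.d_proto[rows], distances.d_ex[rows])
    resp = (rng.random(len(ids)) < r).astype(float)
    if timeout_rate > 0:
        resp[rng.random(len(ids)) < timeout_rate] = np.nan
    is_member = np.array([p.role in ("member", "prototype") for p in items])
    correct = np.where(np.isnan(resp), np.nan, (resp == is_member).astype(float))
    return pd.DataFrame({
        "item_id": ids,
        "role": [p.role for p in items],
        "dl": [p.distortion_level for p in items],
        "response": resp,
        "correct": correct,
    })


def simulate_agent(agent: AgentConfig, sset: StimulusSet, rng: np.random.Generator,
                   criterion: float = 0.75) -> pd.DataFrame:
    """Run one agent through training (with the stop rule) and 8 transfer
    rounds; returns the agent's tidy trial table."""
    from .pipeline import ProtocolState, advance_protocol  # avoid import cycle

    train_items = sset.training_items()
    d_train = ItemDistances.from_stimulus_set(sset, "training")
    d_transfer = ItemDistances.from_stimulus_set(sset, "transfer")
    transfer_items = sset.transfer_items()
    novel_ids = {p.id for p in sset.novel_members + sset.novel_nonmembers} | {sset.prototype.id}

    frames = []
    state = ProtocolState()
    while not state.terminated:
        t = state.round_index + 1
        params = agent.trajectory[min(t, len(agent.trajectory)) - 1]
        df = simulate_round(params, agent.generating_model, train_items, d_train,
                            rng, agent.timeout_rate)
        df.insert(0, "round", t)
        df.insert(0, "phase", "training")
        frames.append(df)
        acc = df["correct"].mean()
        acc = 0.0 if np.isnan(acc) else float(acc)
        state = advance_protocol(state, acc, criterion=criterion)

    for t in range(1, N_TRANSFER_ROUNDS + 1):
        df = simulate_round(agent.transfer_parameters, agent.generating_model,
                            transfer_items, d_transfer, rng, agent.timeout_rate)
        df.insert(0, "round", t)
        df.insert(0, "phase", "transfer")
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "group", agent.group)
    out.insert(0, "subject_id", agent.agent_id)
    out["novelty"] = np.where(out["item_id"].isin(novel_ids), "novel", "training_item")
    return out


def simulate_cohort(config: CohortConfig | None = None) -> BehaviouralDataset:
    """Simulate a two-group cohort; deterministic given the config seeds."""
    cfg = config or CohortConfig()
    sset = build_stimulus_set(cfg.generator, rng_seed=cfg.stimulus_seed)
    ss = np.random.SeedSequence(cfg.seed)
    agent_seeds = ss.spawn(2 * cfg.n_per_group)

    frames, agent_rows = [], []
    i = 0
    for group in GROUPS:
        template = cfg.templates[group]
        mu, sd = TRAIT_SCORE_DISTS[group]
        for j in range(cfg.n_per_group):
            rng = np.random.default_rng(agent_seeds[i])
            agent = AgentConfig.from_template(f"{group}_{j + 1:02d}", group, template,
                                              timeout_rate=cfg.timeout_rate)
            trials = simulate_agent(agent, sset, rng)
            frames.append(trials)
            trait = float(np.clip(np.round(rng.normal(mu, sd)), 0, 50))
            agent_rows.append({
                "subject_id": agent.agent_id,
                "group": group,
                "trait_score": trait,
                "generating_model": agent.generating_model,
                "n_training_rounds": int(trials.loc[trials["phase"] == "training", "round"].max()),
                "k_transfer": agent.transfer_parameters.k,
                "beta_transfer": agent.transfer_parameters.beta,
            })
            i += 1

    provenance = {
        "seed": cfg.seed,
        "stimulus_seed": cfg.stimulus_seed,
        "n_per_group": cfg.n_per_group,
        "timeout_rate": cfg.timeout_rate,
        "templates": {g: asdict(t) for g, t in cfg.templates.items()},
    }
    return BehaviouralDataset(stimuli=sset, trials=pd.concat(frames, ignore_index=True),
                              agents=pd.DataFrame(agent_rows), provenance=provenance)


# ---------------------------------------------------------------------------
# recovery suites


@dataclass
class RecoveryEntry:
    true_params: ParameterSet
    data: EndorsementData
    seed: int


@dataclass
class RecoverySuite:
    """Labelled transfer-phase datasets for parameter/model recovery."""

    model: str
    stimuli: StimulusSet
    entries: list[RecoveryEntry]

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "stimulus_seed": self.stimuli.seed,
            "entries": [
                {
                    "true_params": e.true_params.to_dict(),
                    "seed": e.seed,
                    "item_ids": list(e.data.item_ids),
                    "endorsed": list(e.data.endorsed),
                    "n_obs": list(e.data.n_obs),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path, stimuli: StimulusSet | None = None) -> "RecoverySuite":
        payload = json.loads(Path(path).read_text())
        sset = stimuli or build_stimulus_set(rng_seed=payload["stimulus_seed"])
        entries = [
            RecoveryEntry(
                true_params=ParameterSet.from_dict(rec["true_params"]),
                data=EndorsementData.from_counts(rec["item_ids"], rec["endorsed"], rec["n_obs"]),
                seed=rec["seed"],
            )
            for rec in payload["entries"]
        ]
        return cls(model=payload["model"], stimuli=sset, entries=entries)


def _expand_grid(model: str, grid) -> list[ParameterSet]:
    if isinstance(grid, dict):
        names = list(grid)
        points = [ParameterSet(**dict(zip(names, vals)))
                  for vals in itertools.product(*(grid[n] for n in names))]
    else:
        points = list(grid)
    for ps in points:
        ps.validate(model)
        for name in MODEL_FREE_PARAMS[model]:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(ps, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(f"grid point {name}={v} outside prior bounds ({lo}, {hi})")
    return points


def make_recovery_suite(model: str, grid, n_datasets: int = 1, seed: int = 0,
                        stimulus_seed: int = 20,
                        n_rounds: int = N_TRANSFER_ROUNDS) -> RecoverySuite:
    """Generate ``n_datasets`` labelled transfer datasets per grid point.

    ``grid`` is either a list of ParameterSet or a dict of per-parameter
    value lists (expanded as a cartesian product).  Every dataset simulates
    ``n_rounds`` transfer rounds over the full 41-item set.
    """
    points = _expand_grid(model, grid)
    sset = build_stimulus_set(rng_seed=stimulus_seed)
    dists = ItemDistances.from_stimulus_set(sset, "transfer")
    r_all = {id(ps): predict_endorsement(model, ps, dists.d_proto, dists.d_ex)
             for ps in points}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(points) * n_datasets)]

    entries = []
    idx = 0
    for ps in points:
        r = r_all[id(ps)]
        for _ in range(n_datasets):
            s = child_seeds[idx]
            idx += 1
            rng = np.random.default_rng(s)
            counts = rng.binomial(n_rounds, r).astype(float)
            data = EndorsementData.from_counts(dists.item_ids, counts,
                                               np.full(len(r), float(n_rounds)))
            entries.append(RecoveryEntry(true_params=ps, data=data, seed=s))
    return RecoverySuite(model=model, stimuli=sset, entries=entries)
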