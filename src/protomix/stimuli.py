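"""Posner-style dot-pattern stimuli.

A category is defined by a prototype of nine dots placed on an integer grid.
Category members are distortions of the prototype: every dot is displaced by
a radial jitter whose typical magnitude grows with the distortion level (DL).
Nonmembers are unrelated random nine-dot patterns.  The full inventory holds
41 patterns: the prototype, 20 members and 20 nonmembers, split into a
24-item training set (12 members, 12 nonmembers) and a 41-item transfer set
that adds the prototype plus 8 novel members and 8 novel nonmembers.

Distances between patterns are Euclidean norms in the stacked 18-dimensional
coordinate space (dots matched by index).  Members are rejection-sampled
until they lie within ``member_dmax`` of the prototype and nonmembers until
they lie beyond ``nonmember_dmin``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError, ParseError

logger = logging.getLogger(__name__)

ROLE_PROTOTYPE = "prototype"
ROLE_MEMBER = "member"
ROLE_NONMEMBER = "nonmember"
ROLES = (ROLE_PROTOTYPE, ROLE_MEMBER, ROLE_NONMEMBER)

N_DOTS = 9
DISTORTION_LEVELS = (4, 5, 6, 7)

#: Rayleigh scale (grid units) of the per-dot radial jitter at each level.
#: Chosen so that the expected displacement grows strictly with level while
#: DL7 members still satisfy the member distance ceiling at workable
#: rejection rates.
DEFAULT_DISTORTION_SCALES: dict[int, float] = {4: 0.7, 5: 0.9, 6: 1.1, 7: 1.3}

TRAINING_MEMBER_LEVELS = (5, 5, 5, 5, 6, 6, 6, 6, 7, 7, 7, 7)
NOVEL_MEMBER_LEVELS = (4, 4, 5, 5, 6, 6, 7, 7)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(eq=False)
class DotPattern:
    """One nine-dot stimulus.

    Parameters
    ----------
    id : unique token.
    role : "prototype", "member" or "nonmember".
    dots : (9, 2) array of coordinates in grid units; integer-valued for
        prototypes and nonmembers, real-valued after distortion.
    distortion_level : 4–7 for members, ``None`` otherwise.
    """

    id: str
    role: str
    dots: np.ndarray
    distortion_level: int | None = None

    def __post_init__(self):
        self.dots = np.asarray(self.dots, dtype=float)
        if self.dots.shape != (N_DOTS, 2):
            raise ConfigurationError(
                f"pattern {self.id!r}: expected {N_DOTS} dots, got shape {self.dots.shape}"
            )
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.role == ROLE_MEMBER:
            if self.distortion_level not in DISTORTION_LEVELS:
                raise ConfigurationError(
                    f"member {self.id!r} needs distortion_level in {DISTORTION_LEVELS}, "
                    f"got {self.distortion_level!r}"
                )
        elif self.distortion_level is not None:
            raise ConfigurationError(
                f"{self.role} {self.id!r} must not carry a distortion level"
            )

    def __eq__(self, other):
        if not isinstance(other, DotPattern):
            return NotImplemented
        return (
            self.id == other.id
            and self.role == other.role
            and self.distortion_level == other.distortion_level
            and np.array_equal(self.dots, other.dots)
        )

    def in_canvas(self, canvas: tuple[float, float]) -> bool:
        w, h = canvas
        x, y = self.dots[:, 0], self.dots[:, 1]
        return bool((x >= 0).all() and (x <= w).all() and (y >= 0).all() and (y <= h).all())


@dataclass
class GeneratorConfig:
    """Settings of the stimulus generator.

    ``member_dmax`` / ``nonmember_dmin`` are the prototype-distance
    constraints (18-D Euclidean norm, grid units) enforced by rejection
    sampling.
    """

    canvas: tuple[int, int] = (50, 50)
    margin: int = 10  # prototype dots are placed in the central region
    distortion_scales: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTORTION_SCALES)
    )
    member_dmax: float = 6.22
    nonmember_dmin: float = 12.93
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.member_dmax >= self.nonmember_dmin:
            raise ConfigurationError(
                "member_dmax must be smaller than nonmember_dmin "
                f"({self.member_dmax} >= {self.nonmember_dmin})"
            )


def generate_prototype(
    rng_seed,
    canvas: tuple[int, int] = (50, 50),
    margin: int = 10,
    pattern_id: str = "proto",
    role: str = ROLE_PROTOTYPE,
) -> DotPattern:
    """Place nine distinct dots uniformly on integer grid points in the
    central region of the canvas. Deterministic given the seed."""
    w, h = canvas
    lo_x, hi_x = margin, w - margin
    lo_y, hi_y = margin, h - margin
    n_cells = max(0, hi_x - lo_x + 1) * max(0, hi_y - lo_y + 1)
    if w < 30 or h < 30 or n_cells < N_DOTS:
        raise ConfigurationError(
            f"canvas {canvas} with margin {margin} cannot host {N_DOTS} distinct dots"
        )
    rng = _as_rng(rng_seed)
    seen: set[tuple[int, int]] = set()
    dots = []
    while len(dots) < N_DOTS:
        p = (int(rng.integers(lo_x, hi_x + 1)), int(rng.integers(lo_y, hi_y + 1)))
        if p not in seen:
            seen.add(p)
            dots.append(p)
    return DotPattern(id=pattern_id, role=role, dots=np.array(dots, dtype=float))


def distort_pattern(
    proto: DotPattern,
    level: int,
    rng_seed,
    scales: dict[int, float] | None = None,
    canvas: tuple[int, int] = (50, 50),
    pattern_id: str | None = None,
) -> DotPattern:
    """Displace every prototype dot by an independent radial jitter.

    The jitter radius is Rayleigh with a level-indexed scale, so the expected
    displacement is strictly increasing in level under the default table.
    Dot order is preserved (index correspondence to the prototype).
    """
    scales = dict(DEFAULT_DISTORTION_SCALES) if scales is None else scales
    if level not in scales:
        raise ConfigurationError(f"distortion level {level} not in scale table {sorted(scales)}")
    rng = _as_rng(rng_seed)
    w, h = canvas
    new = np.empty_like(proto.dots)
    for i, (x, y) in enumerate(proto.dots):
        for _ in range(1000):
            r = rng.rayleigh(scales[level]) if scales[level] > 0 else 0.0
            theta = rng.uniform(0.0, 2.0 * np.pi)
            nx, ny = x + r * np.cos(theta), y + r * np.sin(theta)
            if 0 <= nx <= w and 0 <= ny <= h:
                new[i] = (nx, ny)
                break
        else:  # pragma: no cover - unreachable with sane margins
            raise GenerationError(f"could not keep dot {i} inside canvas {canvas}")
    return DotPattern(
        id=pattern_id or f"{proto.id}_dl{level}",
        role=ROLE_MEMBER,
        dots=new,
        distortion_level=level,
    )


def pattern_distance(a: DotPattern, b: DotPattern) -> float:
    """Euclidean norm in the 18-D stacked coordinate space,
    sqrt(sum over dots of dx^2 + dy^2); dots matched by index."""
    if a.dots.shape != b.dots.shape:
        raise ConfigurationError(
            f"dot-count mismatch: {a.dots.shape} vs {b.dots.shape}"
        )
    return float(np.linalg.norm(a.dots - b.dots))


@dataclass(eq=False)
class StimulusSet:
    """The 41-pattern inventory with its training/transfer partition."""

    prototype: DotPattern
    training_members: list[DotPattern]
    training_nonmembers: list[DotPattern]
    novel_members: list[DotPattern]
    novel_nonmembers: list[DotPattern]
    seed: int
    canvas: tuple[int, int] = (50, 50)
    acceptance_rates: dict[str, float] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, StimulusSet):
            return NotImplemented
        return (
            self.seed == other.seed
            and tuple(self.canvas) == tuple(other.canvas)
            and self.all_patterns() == other.all_patterns()
        )

    def all_patterns(self) -> list[DotPattern]:
        return (
            [self.prototype]
            + self.training_members
            + self.training_nonmembers
            + self.novel_members
            + self.novel_nonmembers
        )

    def training_items(self) -> list[DotPattern]:
        """The 24 patterns shown in every training round (no prototype)."""
        return self.training_members + self.training_nonmembers

    def transfer_items(self) -> list[DotPattern]:
        """All 41 patterns shown in every transfer round."""
        return self.all_patterns()

    def members(self) -> list[DotPattern]:
        return self.training_members + self.novel_members

    def nonmembers(self) -> list[DotPattern]:
        return self.training_nonmembers + self.novel_nonmembers

    def by_id(self, pattern_id: str) -> DotPattern:
        for p in self.all_patterns():
            if p.id == pattern_id:
                return p
        raise KeyError(pattern_id)

    def validate(
        self, member_dmax: float = 6.22, nonmember_dmin: float = 12.93
    ) -> None:
        """Raise if any inventory invariant is violated."""
        pats = self.all_patterns()
        if len(pats) != 41:
            raise ConfigurationError(f"inventory holds {len(pats)} patterns, expected 41")
        counts = (
            len(self.training_members),
            len(self.training_nonmembers),
            len(self.novel_members),
            len(self.novel_nonmembers),
        )
        if counts != (12, 12, 8, 8):
            raise ConfigurationError(f"partition sizes {counts} != (12, 12, 8, 8)")
        dls = sorted(p.distortion_level for p in self.training_members)
        if tuple(dls) != tuple(sorted(TRAINING_MEMBER_LEVELS)):
            raise ConfigurationError(f"training member levels {dls}")
        if sorted(p.distortion_level for p in self.novel_members) != sorted(NOVEL_MEMBER_LEVELS):
            raise ConfigurationError("novel member levels must cover DL4-7 twice each")
        ids = [p.id for p in pats]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate pattern ids")
        for p in pats:
            if not p.in_canvas(self.canvas):
                raise ConfigurationError(f"{p.id} leaves canvas {self.canvas}")
        for m in self.members():
            d = pattern_distance(m, self.prototype)
            if d > member_dmax:
                raise ConfigurationError(f"member {m.id} at distance {d:.3f} > {member_dmax}")
        for nm in self.nonmembers():
            d = pattern_distance(nm, self.prototype)
            if d < nonmember_dmin:
                raise ConfigurationError(f"nonmember {nm.id} at distance {d:.3f} < {nonmember_dmin}")


def distance_table(patterns: list[DotPattern]) -> pd.DataFrame:
    """Symmetric pairwise-distance matrix over a pattern list."""
    ids = [p.id for p in patterns]
    coords = np.stack([p.dots.ravel() for p in patterns])  # (n, 18)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    return pd.DataFrame(d, index=ids, columns=ids)


def build_stimulus_set(config: GeneratorConfig | None = None, rng_seed: int = 0) -> StimulusSet:
    """Assemble the full 41-pattern inventory under the distance constraints.

    Members are rejection-sampled until their prototype distance is at most
    ``member_dmax``; nonmembers until theirs is at least ``nonmember_dmin``.
    Acceptance rates are logged and recorded on the returned set.
    """
    cfg = config or GeneratorConfig()
    rng = _as_rng(rng_seed)
    proto = generate_prototype(rng, canvas=cfg.canvas, margin=cfg.margin)

    attempts = {"member": 0, "nonmember": 0}
    accepted = {"member": 0, "nonmember": 0}

    def sample_member(level: int, pattern_id: str) -> DotPattern:
        for _ in range(cfg.max_attempts):
            attempts["member"] += 1
            cand = distort_pattern(
                proto, level, rng, scales=cfg.distortion_scales,
                canvas=cfg.canvas, pattern_id=pattern_id,
            )
            if pattern_distance(cand, proto) <= cfg.member_dmax:
                accepted["member"] += 1
                return cand
        raise GenerationError(
            f"rejection sampling failed for member {pattern_id} (DL{level}): "
            f"distance <= {cfg.member_dmax} not met in {cfg.max_attempts} attempts"
        )

    def sample_nonmember(pattern_id: str) -> DotPattern:
        for _ in range(cfg.max_attempts):
            attempts["nonmember"] += 1
            cand = generate_prototype(
                rng, canvas=cfg.canvas, margin=cfg.margin,
                pattern_id=pattern_id, role=ROLE_NONMEMBER,
            )
            if pattern_distance(cand, proto) >= cfg.nonmember_dmin:
                accepted["nonmember"] += 1
                return cand
        raise GenerationError(
            f"rejection sampling failed for nonmember {pattern_id}: "
            f"distance >= {cfg.nonmember_dmin} not met in {cfg.max_attempts} attempts"
        )

    training_members = [
        sample_member(lvl, f"trm{i + 1:02d}") for i, lvl in enumerate(TRAINING_MEMBER_LEVELS)
    ]
    training_nonmembers = [sample_nonmember(f"trn{i + 1:02d}") for i in range(12)]
    novel_members = [
        sample_member(lvl, f"nvm{i + 1:02d}") for i, lvl in enumerate(NOVEL_MEMBER_LEVELS)
    ]
    novel_nonmembers = [sample_nonmember(f"nvn{i + 1:02d}") for i in range(8)]

    rates = {
        kind: accepted[kind] / attempts[kind] if attempts[kind] else float("nan")
        for kind in attempts
    }
    logger.info("stimulus acceptance rates: %s", rates)

    sset = StimulusSet(
        prototype=proto,
        training_members=training_members,
        training_nonmembers=training_nonmembers,
        novel_members=novel_members,
        novel_nonmembers=novel_nonmembers,
        seed=int(rng_seed) if np.isscalar(rng_seed) else -1,
        canvas=cfg.canvas,
        acceptance_rates=rates,
    )
    sset.validate(cfg.member_dmax, cfg.nonmember_dmin)
    return sset


# ---------------------------------------------------------------------------
# serialization

_ID_PREFIX_TO_SLOT = {
    "trm": "training_members",
    "trn": "training_nonmembers",
    "nvm": "novel_members",
    "nvn": "novel_nonmembers",
}


def write_stimuli(sset: StimulusSet, path) -> None:
    """Write the JSON schema:
    {"seed": int, "canvas": [w, h], "patterns": [{"id","role","dl","dots"}]}.
    Coordinates round-trip bit-exactly (Python float repr)."""
    payload = {
        "seed": sset.seed,
        "canvas": list(sset.canvas),
        "patterns": [
            {
                "id": p.id,
                "role": p.role,
                "dl": p.distortion_level,
                "dots": [[float(x), float(y)] for x, y in p.dots],
            }
            for p in sset.all_patterns()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_stimuli(path) -> StimulusSet:
    """Read a stimulus JSON file written by :func:`write_stimuli`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    try:
        canvas = tuple(payload["canvas"])
        seed = payload["seed"]
        records = payload["patterns"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing top-level field {exc}") from exc

    slots: dict[str, list[DotPattern]] = {v: [] for v in _ID_PREFIX_TO_SLOT.values()}
    proto = None
    for i, rec in enumerate(records):
        try:
            pat = DotPattern(
                id=rec["id"], role=rec["role"],
                dots=np.array(rec["dots"], dtype=float),
                distortion_level=rec["dl"],
            )
        except (KeyError, TypeError, ValueError, ConfigurationError) as exc:
            raise ParseError(f"{path}: bad pattern record {i} ({exc})") from exc
        if pat.role == ROLE_PROTOTYPE:
            proto = pat
        else:
            slot = _ID_PREFIX_TO_SLOT.get(pat.id[:3])
            if slot is None:
                raise ParseError(f"{path}: cannot place pattern id {pat.id!r} in partition")
            slots[slot].append(pat)
    if proto is None:
        raise ParseError(f"{path}: no prototype record")
    return StimulusSet(prototype=proto, seed=seed, canvas=canvas, **slots)


def write_stimuli_csv(sset: StimulusSet, path) -> None:
    """Tidy CSV, one row per dot: pattern_id, role, dl, dot_index, x, y."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pattern_id", "role", "dl", "dot_index", "x", "y"])
        for p in sset.all_patterns():
            for i, (x, y) in enumerate(p.dots):
                w.writerow([p.id, p.role, "" if p.distortion_level is None else p.distortion_level,
                            i, repr(float(x)), repr(float(y))])


def read_stimuli_csv(path, seed: int = -1, canvas=(50, 50)) -> StimulusSet:
    """Rebuild a :class:`StimulusSet` from the dot-level CSV export."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"pattern_id", "role", "dl", "dot_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    slots: dict[str, list[DotPattern]] = {v: [] for v in _ID_PREFIX_TO_SLOT.values()}
    proto = None
    for pid, grp in df.groupby("pattern_id", sort=False):
        grp = grp.sort_values("dot_index")
        if len(grp) != N_DOTS or list(grp["dot_index"]) != list(range(N_DOTS)):
            raise ParseError(
                f"{path}: pattern {pid!r} has dot rows {sorted(grp['dot_index'])}, "
                f"expected 0..{N_DOTS - 1}"
            )
        role = grp["role"].iloc[0]
        dl = grp["dl"].iloc[0]
        dl = None if pd.isna(dl) else int(dl)
        pat = DotPattern(id=str(pid), role=role, dots=grp[["x", "y"]].to_numpy(float),
                         distortion_level=dl)
        if role == ROLE_PROTOTYPE:
            proto = pat
        else:
            slot = _ID_PREFIX_TO_SLOT.get(str(pid)[:3])
            if slot is None:
                raise ParseError(f"{path}: cannot place pattern id {pid!r} in partition")
            slots[slot].append(pat)
    if proto is None:
        raise ParseError(f"{path}: no prototype rows")
    return StimulusSet(prototype=proto, seed=seed, canvas=tuple(canvas), **slots)
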