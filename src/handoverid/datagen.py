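"""Synthetic hand-over study generator.

The experimental design emulated here: two seated participants repeatedly
hand a plastic can across a table. Five binary condition factors (presence of
a platform, beaker size, direct/indirect hand-over signalled by border colour,
full/empty content, and which side gives) are crossed in a full 2^5 factorial;
each of the 32 conditions is repeated ``replicates`` times per pair, in
randomized order. The recorded observable is the time course of the 20
rotational degrees of freedom of each right hand (4 per digit x 5 digits),
global hand pose excluded.

Because the original motion-capture recordings are not publicly deposited,
this module generates trajectories with the *statistical structure* the
analysis downstream assumes:

* a smooth reach-grasp-release template per channel,
* a participant-specific signature (dominant effect),
* additive condition effects (second-order), with the giver-side factor
  inverting the temporal profile,
* a linear trait effect from standardized participant-profile fields
  (weakest effect; zero by default),
* i.i.d. measurement noise, and
* a smooth monotone time warp so that alignment by DTW is non-trivial.

A per-trial Bernoulli "tracking failure" flag emulates the hand-swap failures
of the optical tracker that forced two participants out of the original
analysis; :func:`filter_valid` applies the corresponding exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Sequence

import numpy as np

from ._rng import rng_for
from .errors import EmptyDataError, InvalidArgumentError

__all__ = [
    "FACTOR_NAMES",
    "ConditionFactors",
    "ParticipantProfile",
    "TrialRecord",
    "JointTrajectory",
    "GeneratorConfig",
    "HandoverDataset",
    "generate_design",
    "generate_participants",
    "generate_trajectory",
    "filter_valid",
    "generate_dataset",
]

#: The five binary experimental factors, in canonical order.
FACTOR_NAMES = ("platform", "beaker_size", "handover_kind", "content", "giver_side")

N_CHANNELS = 20  # 4 rotational DoF per digit x 5 digits; global hand pose excluded

BIG_FIVE = ("openness", "conscientiousness", "extraversion", "agreeableness", "neuroticism")

PROFESSIONS = ("student", "staff", "pensioner", "housekeeper")


@dataclass(frozen=True)
class ConditionFactors:
    """One cell of the 2^5 factorial design.

    Encodings: ``platform`` 1 = rack present; ``beaker_size`` 1 = big;
    ``handover_kind`` 1 = indirect (green border); ``content`` 1 = full;
    ``giver_side`` 0 = left participant gives, 1 = right.
    """

    platform: int
    beaker_size: int
    handover_kind: int
    content: int
    giver_side: int

    def __post_init__(self):
        for name in FACTOR_NAMES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise InvalidArgumentError(f"factor {name!r} must be 0 or 1, got {v!r}")

    @classmethod
    def from_index(cls, index: int) -> "ConditionFactors":
        """Decode a condition number in 0..31 (bit i = factor i)."""
        if not 0 <= index < 32:
            raise InvalidArgumentError(f"condition index must be in 0..31, got {index}")
        bits = {name: (index >> i) & 1 for i, name in enumerate(FACTOR_NAMES)}
        return cls(**bits)

    @property
    def index(self) -> int:
        return sum(getattr(self, name) << i for i, name in enumerate(FACTOR_NAMES))

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FACTOR_NAMES}

    @staticmethod
    def full_factorial() -> list["ConditionFactors"]:
        return [ConditionFactors.from_index(i) for i in range(32)]


@dataclass(frozen=True)
class ParticipantProfile:
    """Identity plus the physical/cultural fields and Big Five scores assessed
    per participant before the experiment."""

    identity: str
    gender: str          # "male" | "female"
    age: float           # years
    body_size: float     # metres
    weight: float        # kg
    profession: str
    sportiness: float    # hours of sport per week
    satiety: float       # hours since last meal
    familiarity: int     # 1 (don't know the partner) .. 5
    health: str          # "yes" = problems with arm/shoulder/hand, "no" otherwise
    openness: float
    conscientiousness: float
    extraversion: float
    agreeableness: float
    neuroticism: float

    def __post_init__(self):
        for name in BIG_FIVE:
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise InvalidArgumentError(f"Big Five score {name!r} out of [0, 100]: {v}")
        if self.familiarity not in (1, 2, 3, 4, 5):
            raise InvalidArgumentError(f"familiarity must be in 1..5, got {self.familiarity}")
        for name in ("age", "body_size", "weight", "sportiness", "satiety"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass(frozen=True)
class TrialRecord:
    """One hand-over trial of one pair."""

    trial_index: int
    pair_id: str
    condition: ConditionFactors
    giver_id: str
    receiver_id: str
    replicate: int
    valid: bool = True

    def __post_init__(self):
        if self.giver_id == self.receiver_id:
            raise InvalidArgumentError("giver and receiver must differ")
        if self.replicate < 1:
            raise InvalidArgumentError("replicate numbering starts at 1")

    @property
    def label(self) -> str:
        return f"t{self.trial_index:04d}"

    def participants(self) -> tuple[str, str]:
        return (self.giver_id, self.receiver_id)


@dataclass
class JointTrajectory:
    """T x 20 time course of hand joint angles (radians) for one hand in one trial."""

    values: np.ndarray
    dt: float
    trial_index: int
    owner_id: str
    role: str  # "giver" | "receiver"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise InvalidArgumentError(
                f"trajectory must be T x {N_CHANNELS}, got shape {self.values.shape}"
            )
        if self.values.shape[0] < 2:
            raise InvalidArgumentError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("trajectory contains non-finite values")
        if self.role not in ("giver", "receiver"):
            raise InvalidArgumentError(f"role must be 'giver' or 'receiver', got {self.role!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def label(self) -> str:
        return f"t{self.trial_index:04d}_{self.role}"


@dataclass(frozen=True)
class GeneratorConfig:
    """Effect-size knobs for the synthetic study.

    The default scales encode the hierarchy the analysis probes:
    identity signature >> condition effects >> trait effects (zero by default).
    All sigma_* scales are in radians.
    """

    n_pairs: int = 4
    replicates: int = 3
    sigma_identity: float = 0.6
    sigma_condition: float = 0.25
    sigma_trait: float = 0.0
    sigma_noise: float = 0.08
    warp_jitter: float = 0.08
    failure_rate: float = 0.0
    seed: int = 0
    # plumbing beyond the effect knobs
    t_range: tuple[int, int] = (80, 120)
    dt: float = 0.01
    failing_pairs: tuple[int, ...] = ()
    base_failure_rate: float = 0.0
    failure_threshold: float = 0.5

    def __post_init__(self):
        for name in ("sigma_identity", "sigma_condition", "sigma_trait", "sigma_noise"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        for name in ("failure_rate", "base_failure_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.n_pairs < 1:
            raise InvalidArgumentError("n_pairs must be >= 1")
        if not (2 <= self.t_range[0] <= self.t_range[1]):
            raise InvalidArgumentError("t_range must satisfy 2 <= lo <= hi")
        if not 0 <= self.warp_jitter < 1:
            raise InvalidArgumentError("warp_jitter must be in [0, 1)")

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["t_range"] = list(self.t_range)
        d["failing_pairs"] = list(self.failing_pairs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "t_range" in d:
            d["t_range"] = tuple(d["t_range"])
        if "failing_pairs" in d:
            d["failing_pairs"] = tuple(d["failing_pairs"])
        return cls(**d)

    def study_scale(self) -> "GeneratorConfig":
        """The full study layout: 5 pairs, the last of which suffers total
        tracking failure, so that filtering retains 8 of 10 participants."""
        return replace(self, n_pairs=5, failing_pairs=(4,), failure_rate=1.0)


def generate_design(
    replicates: int,
    seed: int,
    pair_id: str = "pair1",
    participants: tuple[str, str] = ("P1", "P2"),
    start_index: int = 0,
) -> list[TrialRecord]:
    """Randomized full-factorial trial sequence for one giver/receiver pair.

    Returns ``32 * replicates`` trials covering every condition exactly
    ``replicates`` times, in seeded-random order.  ``trial_index`` numbers the
    trials consecutively from ``start_index`` in presentation order.
    """
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    cells = [
        (cond, rep)
        for cond in ConditionFactors.full_factorial()
        for rep in range(1, replicates + 1)
    ]
    rng = rng_for(seed, "design", pair_id)
    order = rng.permutation(len(cells))
    left, right = participants
    if left == right:
        raise InvalidArgumentError("pair members must differ")
    trials = []
    for k, pos in enumerate(order):
        cond, rep = cells[pos]
        giver, receiver = (left, right) if cond.giver_side == 0 else (right, left)
        trials.append(
            TrialRecord(
                trial_index=start_index + k,
                pair_id=pair_id,
                condition=cond,
                giver_id=giver,
                receiver_id=receiver,
                replicate=rep,
            )
        )
    return trials


# Reference location/scale per numeric profile field; chosen to match the
# sampling distributions below so standardization is deterministic per profile
# (no cohort statistics needed).
_TRAIT_REFERENCE = {
    "age": (45.0, 16.0),
    "body_size": (1.72, 0.09),
    "weight": (68.0, 9.0),
    "sportiness": (4.0, 2.3),
    "satiety": (3.0, 1.7),
    "familiarity": (3.0, 1.4),
    "openness": (50.0, 29.0),
    "conscientiousness": (50.0, 29.0),
    "extraversion": (50.0, 29.0),
    "agreeableness": (50.0, 29.0),
    "neuroticism": (50.0, 29.0),
    # binary fields, coded +/-1 before scaling
    "gender": (0.0, 1.0),
    "health": (0.0, 1.0),
}


def _trait_z(profile: ParticipantProfile) -> np.ndarray:
    z = []
    for name, (mu, sd) in _TRAIT_REFERENCE.items():
        if name == "gender":
            v = 1.0 if profile.gender == "female" else -1.0
        elif name == "health":
            v = 1.0 if profile.health == "yes" else -1.0
        else:
            v = float(getattr(profile, name))
        z.append((v - mu) / sd)
    return np.asarray(z)


def generate_participants(n: int, seed: int) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles (n even, >= 2) from plausible ranges.

    Gender alternates so the cohort is balanced; pair members share the same
    familiarity rating (they rate each other).
    """
    if n < 2 or n % 2:
        raise InvalidArgumentError("participant count must be even and >= 2")
    rng = rng_for(seed, "participants")
    profiles = []
    for i in range(n):
        if i % 2 == 0:
            pair_familiarity = int(rng.integers(1, 6))
        profiles.append(
            ParticipantProfile(
                identity=f"P{i + 1}",
                gender="male" if i % 2 == 0 else "female",
                age=float(rng.integers(20, 76)),
                body_size=round(float(np.clip(rng.normal(1.72, 0.09), 1.45, 2.05)), 2),
                weight=round(float(np.clip(rng.normal(68.0, 9.0), 45.0, 110.0)), 1),
                profession=str(rng.choice(PROFESSIONS)),
                sportiness=round(float(rng.uniform(0.0, 8.0)), 1),
                satiety=round(float(rng.uniform(0.0, 6.0)), 1),
                familiarity=pair_familiarity,
                health="yes" if rng.random() < 0.25 else "no",
                **{name: float(rng.integers(0, 101)) for name in BIG_FIVE},
            )
        )
    return profiles


def _bell(s: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((s - center) / width) ** 2)


def _base_template(s: np.ndarray, role: str) -> np.ndarray:
    """Smooth reach-grasp-release profile per channel; the giver acts early in
    the trial, the receiver late, and distal joints lag their proximal ones."""
    out = np.empty((s.size, N_CHANNELS))
    center0 = 0.40 if role == "giver" else 0.60
    for c in range(N_CHANNELS):
        digit, j = divmod(c, 4)
        amp = 1.0 - 0.15 * j + 0.05 * digit
        center = center0 + 0.02 * j
        out[:, c] = amp * _bell(s, center, 0.16) + 0.1 * np.sin(np.pi * s) * np.cos(digit)
    return out


def generate_trajectory(
    trial: TrialRecord,
    profile: ParticipantProfile,
    role: str,
    cfg: GeneratorConfig,
) -> JointTrajectory:
    """One hand's joint-angle time course for one trial.

    Deterministic given (seed, trial, profile, role).  Construction: base
    template + identity signature (fixed per participant) + condition effects
    (the giver-side factor inverts the temporal profile; the other four
    factors add signed shape components) + linear trait effect + i.i.d. noise,
    then a smooth monotone time warp.
    """
    if role not in ("giver", "receiver"):
        raise InvalidArgumentError(f"role must be 'giver' or 'receiver', got {role!r}")
    rng_trial = rng_for(cfg.seed, "trial", trial.pair_id, trial.trial_index, role)
    t_lo, t_hi = cfg.t_range
    T = int(rng_trial.integers(t_lo, t_hi + 1))
    s = np.linspace(0.0, 1.0, T)

    signal = _base_template(s, role)

    # identity signature: constant offsets dominate so the signature survives
    # the temporal inversion caused by the giver-side factor
    rng_id = rng_for(cfg.seed, "identity", profile.identity)
    offsets = rng_id.normal(0.0, cfg.sigma_identity, N_CHANNELS)
    coef_bell = rng_id.normal(0.0, 0.5 * cfg.sigma_identity, N_CHANNELS)
    coef_sin = rng_id.normal(0.0, 0.5 * cfg.sigma_identity, N_CHANNELS)
    signal = signal + offsets
    signal = signal + np.outer(_bell(s, 0.5, 0.25), coef_bell)
    signal = signal + np.outer(np.sin(2 * np.pi * s), coef_sin)

    # additive condition effects (all factors except giver_side)
    for k, name in enumerate(FACTOR_NAMES[:-1]):
        pattern = rng_for(cfg.seed, "cond", name).normal(0.0, cfg.sigma_condition, N_CHANNELS)
        shape = _bell(s, 0.5, 0.3) if k % 2 == 0 else np.sin(np.pi * s)
        sign = 1.0 if getattr(trial.condition, name) == 1 else -1.0
        signal = signal + sign * np.outer(shape, pattern)

    # trait effect: linear in standardized profile fields
    if cfg.sigma_trait > 0:
        z = _trait_z(profile)
        shape = _bell(s, 0.5, 0.3)
        for f, name in enumerate(_TRAIT_REFERENCE):
            pattern = rng_for(cfg.seed, "trait", name).normal(0.0, 1.0, N_CHANNELS)
            pattern /= np.sqrt(len(_TRAIT_REFERENCE))
            signal = signal + cfg.sigma_trait * z[f] * np.outer(shape, pattern)

    # a change of giver side causes a complete inversion of the trajectory
    if trial.condition.giver_side == 1:
        signal = signal[::-1]

    if cfg.sigma_noise > 0:
        signal = signal + rng_trial.normal(0.0, cfg.sigma_noise, (T, N_CHANNELS))

    if cfg.warp_jitter > 0:
        a1, a2 = rng_trial.uniform(-1.0, 1.0, 2)
        sup_grad = np.pi * abs(a1) + 2 * np.pi * abs(a2)
        w = a1 * np.sin(np.pi * s) + a2 * np.sin(2 * np.pi * s)
        u = np.clip(s + cfg.warp_jitter * w / max(1.0, sup_grad), 0.0, 1.0)
        warped = np.empty_like(signal)
        for c in range(N_CHANNELS):
            warped[:, c] = np.interp(u, s, signal[:, c])
        signal = warped

    return JointTrajectory(
        values=signal, dt=cfg.dt, trial_index=trial.trial_index,
        owner_id=profile.identity, role=role,
    )


def filter_valid(
    trials: Sequence[TrialRecord],
    trajectories: Sequence[JointTrajectory] | None = None,
    threshold: float = 0.5,
):
    """Apply the study's validity rule.

    Any participant whose fraction of failed (``valid=False``) trials exceeds
    ``threshold`` is excluded entirely; remaining individually failed trials
    are also dropped.  Returns ``(trials, trajectories, log)`` where ``log``
    records per-participant failure fractions and the exclusion list.
    Raises :class:`EmptyDataError` when nothing survives.
    """
    if not trials:
        raise EmptyDataError("no trials to filter")
    involved: dict[str, list[bool]] = {}
    for t in trials:
        for pid in t.participants():
            involved.setdefault(pid, []).append(not t.valid)
    fractions = {pid: float(np.mean(flags)) for pid, flags in involved.items()}
    excluded = sorted(pid for pid, frac in fractions.items() if frac > threshold)
    kept_trials = [
        t for t in trials
        if t.valid and not any(pid in excluded for pid in t.participants())
    ]
    if not kept_trials:
        raise EmptyDataError("validity filtering removed every trial")
    kept_idx = {t.trial_index for t in kept_trials}
    kept_traj = None
    if trajectories is not None:
        kept_traj = [tr for tr in trajectories if tr.trial_index in kept_idx]
    log = {
        "failure_fractions": fractions,
        "excluded_participants": excluded,
        "n_dropped_trials": len(trials) - len(kept_trials),
    }
    return kept_trials, kept_traj, log


@dataclass
class HandoverDataset:
    """A generated (or loaded) study: profiles, valid trials, and one
    trajectory per (trial, role)."""

    profiles: list[ParticipantProfile]
    trials: list[TrialRecord]
    trajectories: list[JointTrajectory]
    exclusion_log: dict = field(default_factory=dict)

    def profile_of(self, identity: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.identity == identity:
                return p
        raise KeyError(identity)

    @property
    def labels(self) -> list[str]:
        return [tr.label for tr in self.trajectories]

    def to_frame(self):
        """Per-trajectory metadata table: trial bookkeeping, the five condition
        factors, and the owner's full profile."""
        import pandas as pd

        by_index = {t.trial_index: t for t in self.trials}
        rows = []
        for tr in self.trajectories:
            t = by_index[tr.trial_index]
            row = {
                "label": tr.label,
                "trial_index": tr.trial_index,
                "pair_id": t.pair_id,
                "replicate": t.replicate,
                "role": tr.role,
                "participant": tr.owner_id,
            }
            row.update(t.condition.as_dict())
            prof = self.profile_of(tr.owner_id).as_dict()
            prof.pop("identity")
            row.update(prof)
            rows.append(row)
        return pd.DataFrame(rows)


def generate_dataset(cfg: GeneratorConfig) -> HandoverDataset:
    """Full synthetic study: participants, randomized designs per pair,
    failure flags, validity filtering, then trajectories for every retained
    (trial, role)."""
    profiles = generate_participants(2 * cfg.n_pairs, cfg.seed)
    trials: list[TrialRecord] = []
    per_pair = 32 * cfg.replicates
    for p in range(cfg.n_pairs):
        pair_id = f"pair{p + 1}"
        members = (profiles[2 * p].identity, profiles[2 * p + 1].identity)
        design = generate_design(
            cfg.replicates, cfg.seed, pair_id=pair_id, participants=members,
            start_index=p * per_pair,
        )
        rate = cfg.failure_rate if p in cfg.failing_pairs else cfg.base_failure_rate
        if rate > 0:
            rng = rng_for(cfg.seed, "failure", pair_id)
            design = [
                replace(t, valid=bool(rng.random() >= rate)) for t in design
            ]
        trials.extend(design)
    kept, _, log = filter_valid(trials, None, threshold=cfg.failure_threshold)
    kept_participants = sorted(
        {pid for t in kept for pid in t.participants()},
        key=lambda s: int(s[1:]),
    )
    profiles_kept = [p for p in profiles if p.identity in kept_participants]
    prof_by_id = {p.identity: p for p in profiles_kept}
    trajectories = []
    for t in kept:
        trajectories.append(generate_trajectory(t, prof_by_id[t.giver_id], "giver", cfg))
        trajectories.append(generate_trajectory(t, prof_by_id[t.receiver_id], "receiver", cfg))
    return HandoverDataset(
        profiles=profiles_kept, trials=kept, trajectories=trajectories, exclusion_log=log
    )
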