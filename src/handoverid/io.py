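"""Plain-text serialization of every pipeline artifact.

Trajectories are one CSV per (trial, role) with a header ``t,a01..a20`` and a
JSON sidecar holding the trial metadata; design and profile tables, distance
matrices, embeddings and reports are tab-separated text with header rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datagen import (
    FACTOR_NAMES,
    ConditionFactors,
    GeneratorConfig,
    HandoverDataset,
    JointTrajectory,
    N_CHANNELS,
    ParticipantProfile,
    TrialRecord,
)
from .dtw import DistanceMatrix
from .errors import SchemaError
from .nmds import Embedding

__all__ = [
    "write_design", "read_design",
    "write_profiles", "read_profiles",
    "write_trajectory", "read_trajectory",
    "write_dataset", "read_dataset",
    "write_distance_matrix", "read_distance_matrix",
    "write_embedding",
    "save_config", "load_config",
]

_ANGLE_COLS = [f"a{i + 1:02d}" for i in range(N_CHANNELS)]


def write_design(trials: list[TrialRecord], path) -> None:
    rows = []
    for t in trials:
        row = {
            "trial_index": t.trial_index, "pair_id": t.pair_id,
            "giver_id": t.giver_id, "receiver_id": t.receiver_id,
            "replicate": t.replicate, "valid": int(t.valid),
        }
        row.update(t.condition.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design(path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"trial_index", "pair_id", "giver_id", "receiver_id", "replicate",
                "valid", *FACTOR_NAMES}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing design columns {sorted(missing)}")
    trials = []
    for _, r in df.iterrows():
        trials.append(TrialRecord(
            trial_index=int(r.trial_index), pair_id=str(r.pair_id),
            condition=ConditionFactors(**{f: int(r[f]) for f in FACTOR_NAMES}),
            giver_id=str(r.giver_id), receiver_id=str(r.receiver_id),
            replicate=int(r.replicate), valid=bool(r.valid),
        ))
    return trials


def write_profiles(profiles: list[ParticipantProfile], path) -> None:
    pd.DataFrame([p.as_dict() for p in profiles]).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[ParticipantProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        d = r.to_dict()
        try:
            out.append(ParticipantProfile(
                identity=str(d["identity"]), gender=str(d["gender"]),
                age=float(d["age"]), body_size=float(d["body_size"]),
                weight=float(d["weight"]), profession=str(d["profession"]),
                sportiness=float(d["sportiness"]), satiety=float(d["satiety"]),
                familiarity=int(d["familiarity"]), health=str(d["health"]),
                openness=float(d["openness"]),
                conscientiousness=float(d["conscientiousness"]),
                extraversion=float(d["extraversion"]),
                agreeableness=float(d["agreeableness"]),
                neuroticism=float(d["neuroticism"]),
            ))
        except KeyError as e:
            raise SchemaError(f"{path}: missing profile field {e}") from None
    return out


def write_trajectory(traj: JointTrajectory, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / traj.label
    T = traj.n_samples
    df = pd.DataFrame(traj.values, columns=_ANGLE_COLS)
    df.insert(0, "t", np.arange(T) * traj.dt)
    df.to_csv(stem.with_suffix(".csv"), index=False, float_format="%.9g")
    sidecar = {
        "trial_index": traj.trial_index, "owner_id": traj.owner_id,
        "role": traj.role, "dt": traj.dt,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return stem.with_suffix(".csv")


def read_trajectory(csv_path) -> JointTrajectory:
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar for trajectory {csv_path.name}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("trial_index", "owner_id", "role", "dt"):
        if key not in meta:
            raise SchemaError(f"{sidecar_path}: missing field {key!r}")
    df = pd.read_csv(csv_path)
    missing = [c for c in _ANGLE_COLS if c not in df.columns]
    if missing or list(df.columns) != ["t"] + _ANGLE_COLS:
        raise SchemaError(
            f"{csv_path}: expected columns t,{','.join(_ANGLE_COLS)}; "
            f"missing {missing or 'none'}, got {len(df.columns)} columns"
        )
    return JointTrajectory(
        values=df[_ANGLE_COLS].to_numpy(float), dt=float(meta["dt"]),
        trial_index=int(meta["trial_index"]), owner_id=str(meta["owner_id"]),
        role=str(meta["role"]),
    )


def write_dataset(dataset: HandoverDataset, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_design(dataset.trials, directory / "design.tsv")
    write_profiles(dataset.profiles, directory / "profiles.tsv")
    for traj in dataset.trajectories:
        write_trajectory(traj, directory / "trajectories")


def read_dataset(directory) -> HandoverDataset:
    """Load a dataset bundle (generated or externally exported joint angles)."""
    directory = Path(directory)
    trials = read_design(directory / "design.tsv")
    profiles = read_profiles(directory / "profiles.tsv")
    traj_dir = directory / "trajectories"
    if not traj_dir.is_dir():
        raise SchemaError(f"{directory}: missing trajectories/ directory")
    trajectories = [read_trajectory(p) for p in sorted(traj_dir.glob("*.csv"))]
    known = {t.trial_index for t in trials}
    for tr in trajectories:
        if tr.trial_index not in known:
            raise SchemaError(f"trajectory {tr.label}: unknown trial_index {tr.trial_index}")
    return HandoverDataset(profiles=profiles, trials=trials, trajectories=trajectories)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.values, index=D.labels, columns=D.labels).to_csv(
        path, sep="\t", float_format="%.9g"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(values=df.to_numpy(float), labels=[str(c) for c in df.columns])


def write_embedding(emb: Embedding, labels, path) -> None:
    cols = [f"x{i + 1}" for i in range(emb.dim)]
    df = pd.DataFrame(emb.coords, columns=cols)
    df.insert(0, "label", list(labels))
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")
        fh.write(f"# stress1 = {emb.stress:.9g}; iterations = {emb.n_iterations}; "
                 f"converged = {emb.converged}\n")


def save_config(cfg: GeneratorConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))


def load_config(path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))
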