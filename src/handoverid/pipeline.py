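"""End-to-end orchestration: generate -> filter -> distances -> embed ->
classify / code -> statistics, as one reproducible, seeded run.

Every numeric artifact of a run is plain delimited text; a manifest records
the configuration, the fan-out seed and library versions, so re-running with
the same configuration reproduces every output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import seed_for
from .datagen import (
    FACTOR_NAMES,
    GeneratorConfig,
    HandoverDataset,
    generate_dataset,
)
from .dtw import DistanceMatrix, distance_matrix
from .infostats import STATISTIC_NAMES, manova, mi_matrix, model_reduction
from .io import (
    read_dataset,
    write_dataset,
    write_distance_matrix,
    write_embedding,
)
from .lvq import (
    CVPartition,
    LVQConfig,
    evaluate_factor,
    make_partitions,
)
from .nmds import Embedding, NMDSConfig, nmds_embed
from .som import AXIS_NAMES, SOMConfig, bmu_coordinates, cross_validated_codes, som_init, som_train
from .errors import DegenerateLabelsError

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_external_trials"]

#: condition factors = within-subject ("w"); participant properties = between ("b")
PROPERTY_FACTORS = (
    "gender", "age", "body_size", "weight", "profession", "sportiness",
    "satiety", "familiarity", "health", "openness", "conscientiousness",
    "extraversion", "agreeableness", "neuroticism",
)


def stage_seed(seed: int, name: str) -> int:
    """Counter-based fan-out of the global seed to one pipeline stage."""
    return int(seed_for(seed, "stage", name).generate_state(1)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = GeneratorConfig()
    nmds_dims: tuple[int, ...] = (1, 2, 3, 20)
    nmds_max_iter: int = 200
    nmds_tol_fun: float = 1e-4
    nmds_tol_x: float = 1e-4
    nmds_replicates: int = 1
    classify_dim: int = 20  # 3-D separates visually but merges clusters; see docs/methods.md
    trialwise_folds: int = 8
    lvq: LVQConfig = LVQConfig()
    som: SOMConfig = SOMConfig()
    som_dim: int = 20
    n_property_partitions: int = 3
    alpha: float = 0.05
    seed: int = 0
    write_trajectories: bool = True
    make_figures: bool = True


@dataclass
class PipelineResult:
    dataset: HandoverDataset
    frame: pd.DataFrame
    distances: DistanceMatrix
    embeddings: dict[int, Embedding]
    classification_trialwise: pd.DataFrame
    classification_participantwise: pd.DataFrame
    mi: pd.DataFrame
    bmu_codes: np.ndarray
    manova_condition_participant: pd.DataFrame
    property_reduction: tuple
    manova_properties: pd.DataFrame
    outputs: dict = field(default_factory=dict)


def load_external_trials(directory) -> HandoverDataset:
    """Load joint-angle exports in the generator's interchange format
    (design.tsv, profiles.tsv, trajectories/*.csv + sidecars), validated."""
    return read_dataset(directory)


def build_frame(dataset: HandoverDataset) -> pd.DataFrame:
    frame = dataset.to_frame()
    frame["condition"] = sum(
        frame[name].to_numpy() << i for i, name in enumerate(FACTOR_NAMES)
    )
    frame["condition"] = frame["condition"].astype(str)
    return frame


def compute_embeddings(D: DistanceMatrix, cfg: PipelineConfig) -> dict[int, Embedding]:
    out = {}
    for d in cfg.nmds_dims:
        if d > D.n - 1:
            continue
        out[d] = nmds_embed(D, NMDSConfig(
            dim=d, max_iter=cfg.nmds_max_iter, tol_fun=cfg.nmds_tol_fun,
            tol_x=cfg.nmds_tol_x, replicates=cfg.nmds_replicates,
            seed=stage_seed(cfg.seed, f"nmds{d}"),
        ))
    return out


def classification_reports(
    frame: pd.DataFrame, coords: np.ndarray, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Table-4-shaped reports: one row per factor with the mean error, mean
    asymptotic significance and partition count, for trialwise and (for the
    between-subject factors) participantwise cross-validation."""
    n = len(frame)
    lvq_cfg = replace(cfg.lvq, seed=stage_seed(cfg.seed, "lvq"))
    factors = [("w", name) for name in FACTOR_NAMES]
    factors += [("b", "participant")]
    factors += [("b", name) for name in PROPERTY_FACTORS]

    def rows_for(cv: CVPartition, designs: set[str]):
        rows = []
        for design, factor in factors:
            if design not in designs:
                continue
            try:
                ev = evaluate_factor(
                    coords, frame[factor], cv, lvq_cfg, design=design, factor=factor
                )
            except DegenerateLabelsError:
                continue  # every fold lacked training coverage of some class
            rows.append({
                "design": ev.design, "factor": ev.factor, "error": ev.mean_error,
                "asymptotic_significance": ev.mean_asymptotic_significance,
                "N": ev.n_partitions,
            })
        return pd.DataFrame(rows)

    trial_cv = make_partitions(n, "trialwise", k=min(cfg.trialwise_folds, n),
                               seed=stage_seed(cfg.seed, "cv-trial"))
    part_cv = make_partitions(n, "participantwise",
                              participants=frame["participant"])
    trialwise = rows_for(trial_cv, {"w", "b"})
    participantwise = rows_for(part_cv, {"b"})
    return trialwise, participantwise


def mi_factor_frame(frame: pd.DataFrame, embeddings: dict[int, Embedding]) -> pd.DataFrame:
    """Factor table for the MI matrix: participant properties, identity, the
    five condition factors, and every projection component at each requested
    dimensionality (1, 2, 3, 20 by default)."""
    cols = {}
    for name in PROPERTY_FACTORS:
        cols[name] = frame[name]
    cols["identity"] = frame["participant"]
    for name in FACTOR_NAMES:
        cols[name] = frame[name]
    comp_names = {1: ["tr"], 2: ["t2x", "t2y"], 3: ["t3x", "t3y", "t3z"]}
    for d, emb in sorted(embeddings.items()):
        names = comp_names.get(d, [f"c{i + 1:02d}" for i in range(d)])
        for j, nm in enumerate(names):
            cols[nm] = emb.coords[:, j]
    return pd.DataFrame(cols)


def _estimable_columns(Y: np.ndarray, frame: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Greedy left-to-right selection of response columns whose *residuals*
    (after fitting the model terms) stay linearly independent, so the MANOVA
    error matrix is nonsingular."""
    from .infostats import design_matrix

    X = design_matrix(frame, terms)
    B, _, _, _ = np.linalg.lstsq(X, Y.astype(float), rcond=None)
    R = Y - X @ B
    scale = max(np.abs(R).max(), 1e-12)
    keep: list[int] = []
    for j in range(Y.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(R[:, trial], tol=1e-7 * scale) == len(trial):
            keep.append(j)
    return np.asarray(keep, dtype=int)


def _fold_coded_responses(
    X: np.ndarray, cv: CVPartition, som_cfg: SOMConfig
) -> list[np.ndarray]:
    """For each fold: train a map on the complement and code *all* trials with
    it (a held-out fold holds one participant only, so a participant term is
    estimable only on the full coded set)."""
    out = []
    for k, fold in enumerate(cv.folds):
        train_idx = cv.complement(k) if cv.n_folds > 1 else fold
        lattice = som_init(X.shape[1], seed=som_cfg.seed + k, data=X[train_idx])
        lattice = som_train(lattice, X[train_idx], epochs=som_cfg.epochs,
                            lr0=som_cfg.lr0, radius0=som_cfg.radius0,
                            seed=som_cfg.seed + k)
        out.append(bmu_coordinates(lattice, X))
    return out


def manova_condition_participant(
    frame: pd.DataFrame, X: np.ndarray, cfg: PipelineConfig
) -> tuple[pd.DataFrame, list]:
    """Table-5-shaped MANOVA: BMU coordinates against condition + participant,
    one map per participantwise fold, mean p over folds per statistic."""
    cv = make_partitions(len(frame), "participantwise",
                         participants=frame["participant"])
    som_cfg = replace(cfg.som, seed=stage_seed(cfg.seed, "som-manova"))
    fold_codes = _fold_coded_responses(X, cv, som_cfg)
    pvals: dict[tuple[str, str], list[float]] = {}
    per_fold = []
    for codes in fold_codes:
        keep = _estimable_columns(codes, frame, ["condition", "participant"])
        res = manova(codes[:, keep], frame, ["condition", "participant"])
        per_fold.append(res)
        for term in res.terms:
            for stat in STATISTIC_NAMES:
                pvals.setdefault((term, stat), []).append(res.terms[term][stat].p)
    rows = [
        {"factor": term, "statistic": stat,
         "mean_asymptotic_significance": float(np.mean(ps)), "N": len(ps)}
        for (term, stat), ps in pvals.items()
    ]
    return pd.DataFrame(rows), per_fold


def manova_properties(
    frame: pd.DataFrame, X: np.ndarray, cfg: PipelineConfig
) -> tuple[list, pd.DataFrame]:
    """Table-6-shaped MANOVA after backward model reduction over the
    participant-property candidates, evaluated jointly on a few trialwise
    partitions (one trained map each)."""
    cv = make_partitions(len(frame), "trialwise",
                         k=cfg.n_property_partitions,
                         seed=stage_seed(cfg.seed, "cv-props"))
    som_cfg = replace(cfg.som, seed=stage_seed(cfg.seed, "som-props"))
    fold_codes = _fold_coded_responses(X, cv, som_cfg)
    fold_codes = [
        codes[:, _estimable_columns(codes, frame, list(PROPERTY_FACTORS))]
        for codes in fold_codes
    ]
    retained, results = model_reduction(
        fold_codes, frame, list(PROPERTY_FACTORS), alpha=cfg.alpha
    )
    rows = []
    for term in (["(intercept)"] + retained) if retained else []:
        row = {"factor": term}
        for k, res in enumerate(results):
            row[f"p_partition{k + 1}"] = res.p(term, "Wilks")
        rows.append(row)
    return (retained, results), pd.DataFrame(rows)


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    dataset: HandoverDataset | None = None,
) -> PipelineResult:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Any stage failure aborts with the stage name after writing a partial
    manifest. When ``dataset`` is given, the generation stage is skipped and
    the provided (already filtered) data are analysed instead."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    completed: list[str] = []
    t0 = time.time()

    def _manifest(path_name: str):
        cfg_json = json.dumps(
            {"generator": cfg.generator.as_dict(),
             "pipeline": {k: getattr(cfg, k) for k in (
                 "nmds_dims", "nmds_max_iter", "nmds_tol_fun", "nmds_tol_x",
                 "nmds_replicates", "classify_dim", "trialwise_folds",
                 "som_dim", "n_property_partitions", "alpha", "seed")}},
            default=list, sort_keys=True)
        manifest = {
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "stages_completed": list(completed),
            "outputs": dict(outputs),
            "elapsed_s": round(time.time() - t0, 3),
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (outdir / path_name).write_text(json.dumps(manifest, indent=1))

    stage = "generate"
    try:
        if dataset is None:
            gen = replace(cfg.generator, seed=stage_seed(cfg.seed, "generator"))
            dataset = generate_dataset(gen)
        frame = build_frame(dataset)
        if cfg.write_trajectories:
            write_dataset(dataset, outdir)
        else:
            from .io import write_design, write_profiles
            write_design(dataset.trials, outdir / "design.tsv")
            write_profiles(dataset.profiles, outdir / "profiles.tsv")
        outputs["design"] = "design.tsv"
        outputs["profiles"] = "profiles.tsv"
        completed.append(stage)

        stage = "distances"
        D = distance_matrix(dataset.trajectories)
        write_distance_matrix(D, outdir / "dtw_distances.tsv")
        outputs["distances"] = "dtw_distances.tsv"
        completed.append(stage)

        stage = "embed"
        embeddings = compute_embeddings(D, cfg)
        for d, emb in embeddings.items():
            name = f"embedding_d{d}.tsv"
            write_embedding(emb, D.labels, outdir / name)
            outputs[f"embedding_d{d}"] = name
        if cfg.make_figures and 3 in embeddings:
            from .plots import embedding_scatter
            embedding_scatter(
                embeddings[3].coords, frame["participant"], frame["role"],
                outdir / "embedding_d3.png",
                title=f"NMDS (dim 3), stress1={embeddings[3].stress:.3f}",
            )
        completed.append(stage)

        stage = "classify"
        cdim = cfg.classify_dim if cfg.classify_dim in embeddings else max(embeddings)
        coords = embeddings[cdim].coords
        trialwise, participantwise = classification_reports(frame, coords, cfg)
        trialwise.to_csv(outdir / "classification_trialwise.tsv", sep="\t",
                         index=False, float_format="%.6g")
        participantwise.to_csv(outdir / "classification_participantwise.tsv",
                               sep="\t", index=False, float_format="%.6g")
        outputs["classification_trialwise"] = "classification_trialwise.tsv"
        outputs["classification_participantwise"] = "classification_participantwise.tsv"
        completed.append(stage)

        stage = "mutual_information"
        mi = mi_matrix(mi_factor_frame(frame, embeddings))
        mi.to_csv(outdir / "mi_matrix.tsv", sep="\t", float_format="%.6g")
        outputs["mi_matrix"] = "mi_matrix.tsv"
        if cfg.make_figures:
            from .plots import mi_heatmap
            mi_heatmap(mi, outdir / "mi_matrix.png")
        completed.append(stage)

        stage = "som"
        sdim = cfg.som_dim if cfg.som_dim in embeddings else max(embeddings)
        X = embeddings[sdim].coords
        som_cfg = replace(cfg.som, seed=stage_seed(cfg.seed, "som-codes"))
        part_cv = make_partitions(len(frame), "participantwise",
                                  participants=frame["participant"])
        codes = cross_validated_codes(X, part_cv, som_cfg)
        code_df = pd.DataFrame(codes, columns=list(AXIS_NAMES))
        code_df.insert(0, "label", frame["label"])
        code_df.to_csv(outdir / "bmu_codes.tsv", sep="\t", index=False)
        outputs["bmu_codes"] = "bmu_codes.tsv"
        completed.append(stage)

        stage = "manova"
        table5, _ = manova_condition_participant(frame, X, cfg)
        table5.to_csv(outdir / "manova_condition_participant.tsv", sep="\t",
                      index=False, float_format="%.6g")
        outputs["manova_condition_participant"] = "manova_condition_participant.tsv"
        reduction, table6 = manova_properties(frame, X, cfg)
        table6.to_csv(outdir / "manova_properties.tsv", sep="\t",
                      index=False, float_format="%.6g")
        outputs["manova_properties"] = "manova_properties.tsv"
        completed.append(stage)
    except Exception as e:
        _manifest("manifest.partial.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    _manifest("manifest.json")
    return PipelineResult(
        dataset=dataset, frame=frame, distances=D, embeddings=embeddings,
        classification_trialwise=trialwise,
        classification_participantwise=participantwise,
        mi=mi, bmu_codes=codes,
        manova_condition_participant=table5,
        property_reduction=reduction,
        manova_properties=table6,
        outputs=outputs,
    )
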