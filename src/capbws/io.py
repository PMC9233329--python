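"""CSV formats, run configuration and the end-to-end pipeline.

All files are comma-separated UTF-8 with a mandatory header and 1-based item,
task and level indices.  Every output file gets a JSON metadata sidecar
(``<name>.meta.json``) recording the package version, the seed and a hash of
the run configuration, so that a rerun with an identical configuration is
byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import (
    PopulationConfig,
    ResponseSet,
    default_population_config,
    simulate_population,
    simulate_responses,
)
from .compare import cohort_rank_table, pearson_matrix
from .design import Design, generate_design, validate_design
from .hb import McmcConfig, Posterior, compute_ris, filter_inconsistent, fit_hb
from .instrument import DEFAULT_SPEC
from .regression import (
    hb_ris_pipeline,
    identity_pipeline,
    jackknife_robust,
    significance_table,
)
from .weights import build_weight_set, weight_set_frame, weight_set_from_frame

logger = logging.getLogger("capbws")

__all__ = [
    "read_design",
    "write_design",
    "read_responses",
    "write_responses",
    "read_weight_set",
    "write_weight_set",
    "RunConfig",
    "run_pipeline",
]

_DESIGN_COLUMNS = ["version", "task", "position", "item_id"]
_RESPONSE_COLUMNS = [
    "respondent_id", "cohort", "gender", "version", "task",
    "best_item", "worst_item",
]


class ParseError(ValueError):
    """A CSV file does not conform to the documented schema."""


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _as_int(frame: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for c in columns:
        converted = pd.to_numeric(frame[c], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            line = int(frame.index[bad][0]) + 2  # header is line 1
            raise ParseError(f"{path}: non-integer value in column {c!r} at line {line}")
        frame[c] = converted.astype(int)
    return frame


def write_design(design: Design, path) -> None:
    """One row per displayed attribute: version, task, position, item_id."""
    rows = []
    for v in range(1, design.n_versions + 1):
        tasks = design.tasks(v)
        for t in range(1, design.n_tasks + 1):
            for p in range(1, design.set_size + 1):
                rows.append((v, t, p, int(tasks[t - 1, p - 1])))
    pd.DataFrame(rows, columns=_DESIGN_COLUMNS).to_csv(path, index=False)


def read_design(path) -> Design:
    """Parse and structurally validate a design CSV.

    Validation delegates to :func:`capbws.design.validate_design`, so
    duplicate items within a task are rejected with the offending task named.
    """
    frame = pd.read_csv(path)
    _require_columns(frame, _DESIGN_COLUMNS, path)
    frame = _as_int(frame, _DESIGN_COLUMNS, path)
    dup = frame.duplicated(subset=["version", "task", "position"])
    if dup.any():
        line = int(frame.index[dup][0]) + 2
        raise ParseError(f"{path}: duplicate (version, task, position) at line {line}")
    versions = []
    n_items = int(frame["item_id"].max())
    v_labels = sorted(frame["version"].unique())
    if v_labels != list(range(1, len(v_labels) + 1)):
        raise ParseError(f"{path}: versions must be numbered 1..n, got {v_labels}")
    set_size = int(frame["position"].max())
    n_tasks = int(frame["task"].max())
    for v in v_labels:
        sub = frame[frame["version"] == v]
        if len(sub) != n_tasks * set_size:
            raise ParseError(
                f"{path}: version {v} has {len(sub)} rows, expected "
                f"{n_tasks * set_size}"
            )
        tasks = np.zeros((n_tasks, set_size), dtype=np.int64)
        for _, row in sub.iterrows():
            tasks[row["task"] - 1, row["position"] - 1] = row["item_id"]
        if np.any(tasks == 0):
            raise ParseError(f"{path}: version {v} has missing (task, position) cells")
        versions.append(tasks)
    design = Design(
        n_items=n_items, set_size=set_size, versions=tuple(versions)
    )
    validate_design(design)
    return design


def write_responses(responses: ResponseSet, path) -> None:
    """Long-format response CSV including respondent covariates."""
    merged = responses.responses.merge(
        responses.respondents[["respondent_id", "cohort", "gender", "version"]],
        on="respondent_id",
    )[_RESPONSE_COLUMNS]
    merged.to_csv(path, index=False)


def read_responses(path, design: Design) -> ResponseSet:
    """Parse responses and cross-validate them against the design.

    Picked items must be shown in the referenced task; best must differ from
    worst.  Respondents with fewer than n_tasks valid rows are dropped with a
    logged count (complete-case rule).
    """
    frame = pd.read_csv(path)
    _require_columns(frame, _RESPONSE_COLUMNS, path)
    frame = _as_int(
        frame, ["respondent_id", "version", "task", "best_item", "worst_item"], path
    )
    bad_version = ~frame["version"].isin(range(1, design.n_versions + 1))
    if bad_version.any():
        line = int(frame.index[bad_version][0]) + 2
        raise ParseError(
            f"{path}: unknown version {frame['version'][bad_version].iloc[0]} "
            f"at line {line}"
        )
    for _, row in frame.iterrows():
        shown = design.tasks(int(row["version"]))[int(row["task"]) - 1]
        if row["best_item"] == row["worst_item"]:
            raise ParseError(
                f"{path}: respondent {row['respondent_id']} task {row['task']}: "
                "best equals worst"
            )
        for col in ("best_item", "worst_item"):
            if row[col] not in shown:
                raise ParseError(
                    f"{path}: respondent {row['respondent_id']} task "
                    f"{row['task']}: {col} {row[col]} not in shown set "
                    f"{shown.tolist()}"
                )
    counts = frame.groupby("respondent_id").size()
    complete = counts[counts == design.n_tasks].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning(
            "dropping %d incomplete respondent(s): %s", len(dropped), dropped
        )
    frame = frame[frame["respondent_id"].isin(complete)]
    respondents = (
        frame[["respondent_id", "cohort", "gender", "version"]]
        .drop_duplicates("respondent_id")
        .reset_index(drop=True)
    )
    responses = frame[["respondent_id", "task", "best_item", "worst_item"]].reset_index(
        drop=True
    )
    return ResponseSet(respondents=respondents, responses=responses, design=design)


def write_weight_set(ws, path, decimals: int = 4) -> None:
    weight_set_frame(ws, decimals).to_csv(path, index=False)


def read_weight_set(path, spec=DEFAULT_SPEC):
    return weight_set_from_frame(pd.read_csv(path), spec)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end synthetic run.

    The global seed derives independent per-stage seeds, so any prefix of the
    pipeline is reproducible in isolation.
    """

    seed: int = 20220624
    n_items: int = 16
    set_size: int = 6
    n_tasks: int = 16
    n_versions: int = 3
    design_iterations: int = 20
    mcmc_profile: str = "reduced"
    rlh_threshold: float = 0.2
    jackknife: bool = False
    jackknife_hb: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def mcmc(self, seed: int) -> McmcConfig:
        if self.mcmc_profile == "full":
            return McmcConfig(seed=seed)
        return McmcConfig.reduced(seed=seed)


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _write_with_sidecar(frame: pd.DataFrame, path: Path, config: RunConfig,
                        stage: str, seed: int) -> str:
    frame.to_csv(path, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    sidecar = {
        "stage": stage,
        "seed": seed,
        "config_hash": config.config_hash(),
        "capbws_version": __version__,
        "sha256": digest,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )
    return digest


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Simulate, fit, score, compare, regress and weight in one audited run.

    Writes design.csv, responses.csv, posterior.csv, ris.csv, comparison.csv,
    correlation.csv, regression.csv and weights.csv to ``out_dir``, plus a
    manifest.json of stage seeds and file hashes.  Reruns with the same
    configuration produce identical hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 5)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "capbws_version": __version__,
        "stage_seeds": dict(
            zip(["design", "population", "responses", "mcmc", "jackknife"], seeds)
        ),
        "files": {},
        "stages": {},
    }

    def record(stage, name, frame, seed):
        digest = _write_with_sidecar(frame, out / name, config, stage, seed)
        manifest["files"][name] = digest
        manifest["stages"][stage] = "complete"

    try:
        design = generate_design(
            config.n_items, config.set_size, config.n_tasks,
            config.n_versions, config.design_iterations, seeds[0],
        )
        write_design(design, out / "design.csv")
        manifest["files"]["design.csv"] = hashlib.sha256(
            (out / "design.csv").read_bytes()
        ).hexdigest()
        manifest["stages"]["design"] = "complete"

        pop = default_population_config(seed=seeds[1])
        truths = simulate_population(pop)
        responses = simulate_responses(design, truths, seed=seeds[2])
        write_responses(responses, out / "responses.csv")
        manifest["files"]["responses.csv"] = hashlib.sha256(
            (out / "responses.csv").read_bytes()
        ).hexdigest()
        manifest["stages"]["simulate"] = "complete"

        posterior = fit_hb(responses, config=config.mcmc(seeds[3]))
        included, excluded = filter_inconsistent(posterior, config.rlh_threshold)
        post_frame = pd.DataFrame(
            {
                "respondent_id": posterior.respondents["respondent_id"],
                "rlh": posterior.rlh,
                "included": np.isin(
                    posterior.respondents["respondent_id"], included
                ).astype(int),
            }
        )
        for k in range(posterior.n_items):
            post_frame[f"beta_{k + 1}"] = posterior.beta_mean[:, k]
        record("fit", "posterior.csv", post_frame, seeds[3])

        ris = compute_ris(posterior, include_ids=included)
        record("ris", "ris.csv", ris.summary, seeds[3])

        mask = np.isin(posterior.respondents["respondent_id"], included)
        cov = posterior.respondents[mask].reset_index(drop=True)
        comparison = cohort_rank_table(ris.ris_individual, cov["cohort"].to_numpy())
        record("compare", "comparison.csv", comparison, seeds[3])
        corr = pearson_matrix(ris.ris_individual)
        corr_frame = pd.DataFrame(
            corr, columns=[f"item_{k + 1}" for k in range(corr.shape[0])]
        )
        corr_frame.insert(0, "item", np.arange(1, corr.shape[0] + 1))
        record("correlate", "correlation.csv", corr_frame, seeds[3])

        if config.jackknife:
            if config.jackknife_hb:
                pipeline = hb_ris_pipeline(
                    _subset_responses(responses, included),
                    config.mcmc(seeds[4]),
                )
            else:
                pipeline = identity_pipeline(ris.ris_individual)
            jk = jackknife_robust(pipeline, cov)
            table = significance_table(
                jk, ris.ris_individual, DEFAULT_SPEC.item_labels
            )
            record("regress", "regression.csv", table, seeds[4])

        ws = build_weight_set(ris.ris_mean)
        record("weights", "weights.csv", weight_set_frame(ws), seeds[3])
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _subset_responses(responses: ResponseSet, ids) -> ResponseSet:
    keep = set(np.asarray(ids).tolist())
    resp = responses.respondents[
        responses.respondents["respondent_id"].isin(keep)
    ].reset_index(drop=True)
    rows = responses.responses[
        responses.responses["respondent_id"].isin(keep)
    ].reset_index(drop=True)
    return ResponseSet(respondents=resp, responses=rows, design=responses.design)
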