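"""Orchestrate the full factorial imputation benchmark.

The experiment grid is cohorts x mechanisms x scales x methods x
repetitions.  For one cohort, mechanism and repetition the masking seed
is shared, so every scale and every method imputes the identical set of
simulated missing positions; with the default five mechanisms, two
scales and one hundred repetitions each method performs 1000 imputation
runs per dataset (500 per scale).  Individual task failures are logged
and recorded as absent cells; they never abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .evaluation import BinScore, ScoreRecord, profile_by_range, score_imputation
from .imputation import ImputerSpec, METHODS, run_imputer
from .matrix import MethylMatrix, Scale, read_matrix_tsv
from .missingness import Mechanism, simulate
from .comparison import render_report, summarize_table
from .representation import convert_matrix
from .synthetic import CohortConfig, PropensityProfile, generate_cohort
from .missingness import estimate_mar_weights

__all__ = ["CohortRef", "BenchmarkConfig", "Task", "TaskPlan", "plan_tasks", "run_benchmark"]

logger = logging.getLogger(__name__)


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string-able parts."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class CohortRef:
    """One benchmark cohort: either a generator config or a matrix file."""

    name: str
    status: str = "healthy"
    config: CohortConfig | None = None
    path: str | None = None

    def __post_init__(self) -> None:
        if (self.config is None) == (self.path is None):
            raise ValueError("CohortRef needs exactly one of config or path")


def _default_mechanisms() -> list[Mechanism]:
    return list(Mechanism)


def _default_scales() -> list[Scale]:
    return [Scale.BETA, Scale.M]


def _default_methods() -> list[ImputerSpec]:
    return [ImputerSpec(m) for m in METHODS]


@dataclass
class BenchmarkConfig:
    cohorts: list[CohortRef]
    mechanisms: list[Mechanism] = field(default_factory=_default_mechanisms)
    scales: list[Scale] = field(default_factory=_default_scales)
    methods: list[ImputerSpec] = field(default_factory=_default_methods)
    repetitions: int = 100
    fraction: float = 0.03
    alpha: float = 0.05
    base_seed: int = 0
    outdir: str | Path = "benchmark_out"

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("cohorts must be non-empty")
        self.mechanisms = [Mechanism(m) for m in self.mechanisms]
        self.scales = [Scale(s) for s in self.scales]
        if not self.mechanisms or not self.scales or not self.methods:
            raise ValueError("mechanisms, scales and methods must be non-empty")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "cohorts": [
                    (c.name, c.status, repr(c.config), c.path) for c in self.cohorts
                ],
                "mechanisms": [m.value for m in self.mechanisms],
                "scales": [s.value for s in self.scales],
                "methods": [(m.method, sorted(m.params.items()), m.clip_beta) for m in self.methods],
                "repetitions": self.repetitions,
                "fraction": self.fraction,
                "alpha": self.alpha,
                "base_seed": self.base_seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


class Task(NamedTuple):
    cohort: str
    mechanism: Mechanism
    scale: Scale
    method: str
    repetition: int
    mask_seed: int
    method_seed: int


@dataclass
class TaskPlan:
    tasks: list[Task]

    def __len__(self) -> int:
        return len(self.tasks)

    def runs_per_dataset_per_method(self) -> int:
        cohorts = {t.cohort for t in self.tasks}
        methods = {t.method for t in self.tasks}
        return len(self.tasks) // (len(cohorts) * len(methods))


def plan_tasks(cfg: BenchmarkConfig) -> TaskPlan:
    """Deterministic task enumeration.

    The masking seed depends only on (cohort, mechanism, repetition), so
    both scales and all methods of a repetition see identical masked
    positions; method-internal randomness gets its own derived seed.
    """
    tasks = []
    for cohort in cfg.cohorts:
        for mech in cfg.mechanisms:
            for rep in range(cfg.repetitions):
                mask_seed = stable_seed(cfg.base_seed, cohort.name, mech.value, rep)
                for scale in cfg.scales:
                    for spec in cfg.methods:
                        tasks.append(
                            Task(
                                cohort.name,
                                mech,
                                scale,
                                spec.method,
                                rep,
                                mask_seed,
                                stable_seed(mask_seed, spec.method),
                            )
                        )
    return TaskPlan(tasks)


def _resolve_cohort(ref: CohortRef) -> tuple[MethylMatrix, PropensityProfile]:
    if ref.config is not None:
        return generate_cohort(ref.config)
    x = read_matrix_tsv(ref.path)
    if x.n_missing:
        profile = estimate_mar_weights(x.mask)
    else:
        profile = PropensityProfile.uniform(x.n_cpgs)
    return x, profile


def _records_to_frames(records: list[ScoreRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    score_rows, bin_rows = [], []
    for r in records:
        score_rows.append(
            dict(
                dataset=r.dataset,
                status=r.status,
                method=r.method,
                scale=r.scale,
                mechanism=r.mechanism,
                repetition=r.repetition,
                n_scored=r.n_scored,
                n_ignored=r.n_ignored,
                mae=r.mae,
                rmse=r.rmse,
            )
        )
        for b in r.per_bin:
            bin_rows.append(
                dict(
                    dataset=r.dataset,
                    status=r.status,
                    method=r.method,
                    scale=r.scale,
                    mechanism=r.mechanism,
                    repetition=r.repetition,
                    lo=b.lo,
                    hi=b.hi,
                    n=b.n,
                    mae=b.mae,
                    rmse=b.rmse,
                )
            )
    return pd.DataFrame(score_rows), pd.DataFrame(bin_rows)


def _records_from_frames(scores: pd.DataFrame, bins: pd.DataFrame) -> list[ScoreRecord]:
    key_cols = ["dataset", "method", "scale", "mechanism", "repetition"]
    bin_map: dict[tuple, list[BinScore]] = {}
    if len(bins):
        for key, g in bins.groupby(key_cols, sort=False):
            bin_map[key] = [
                BinScore(row.lo, row.hi, int(row.n), row.mae, row.rmse)
                for row in g.itertuples()
            ]
    records = []
    for row in scores.itertuples():
        key = (row.dataset, row.method, row.scale, row.mechanism, row.repetition)
        records.append(
            ScoreRecord(
                dataset=row.dataset,
                method=row.method,
                scale=row.scale,
                mechanism=row.mechanism,
                repetition=int(row.repetition),
                n_scored=int(row.n_scored),
                n_ignored=int(row.n_ignored),
                mae=row.mae,
                rmse=row.rmse,
                per_bin=bin_map.get(key, []),
                status=row.status,
            )
        )
    return records


def run_benchmark(cfg: BenchmarkConfig) -> list[ScoreRecord]:
    """Execute the plan and write all report artifacts under cfg.outdir.

    Artifacts: ``scores.csv`` (long format), ``bins.csv`` (per-bin
    companion), ``profile.csv`` (per-beta-range aggregates),
    ``comparison/`` (per-stratum tables + JSON report) and
    ``run_meta.json``.  Re-running with the same config resumes: tasks
    whose scores are already on disk (verified via the config hash) are
    skipped.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_path = outdir / "run_meta.json"
    scores_path = outdir / "scores.csv"
    bins_path = outdir / "bins.csv"

    done_records: list[ScoreRecord] = []
    if meta_path.exists() and scores_path.exists():
        try:
            meta = json.loads(meta_path.read_text())
            if meta.get("config_hash") == cfg.config_hash():
                bins_df = (
                    pd.read_csv(bins_path, float_precision="round_trip")
                    if bins_path.exists()
                    else pd.DataFrame()
                )
                done_records = _records_from_frames(
                    pd.read_csv(scores_path, float_precision="round_trip"), bins_df
                )
                logger.info("resuming: %d records already on disk", len(done_records))
        except Exception:
            logger.exception("could not resume from %s; recomputing", outdir)
            done_records = []
    done_keys = {
        (r.dataset, r.mechanism, r.scale, r.method, r.repetition) for r in done_records
    }

    cohorts = {ref.name: (ref, *_resolve_cohort(ref)) for ref in cfg.cohorts}
    spec_by_method = {s.method: s for s in cfg.methods}

    records = list(done_records)
    n_failed = 0
    for ref in cfg.cohorts:
        _, matrix, profile = cohorts[ref.name]
        for mech in cfg.mechanisms:
            for rep in range(cfg.repetitions):
                todo = [
                    (scale, spec)
                    for scale in cfg.scales
                    for spec in cfg.methods
                    if (ref.name, mech.value, scale.value, spec.method, rep) not in done_keys
                ]
                if not todo:
                    continue
                mask_seed = stable_seed(cfg.base_seed, ref.name, mech.value, rep)
                try:
                    masked = simulate(
                        matrix, mech, cfg.fraction, weights=profile, seed=mask_seed
                    )
                except Exception:
                    logger.exception(
                        "masking failed: cohort=%s mechanism=%s rep=%d", ref.name, mech, rep
                    )
                    n_failed += len(todo)
                    continue
                converted = {}
                for scale, spec in todo:
                    try:
                        if scale not in converted:
                            converted[scale] = convert_matrix(masked.matrix, scale)
                        run_spec = ImputerSpec(
                            spec.method,
                            spec.params,
                            clip_beta=spec.clip_beta,
                            seed=stable_seed(mask_seed, spec.method),
                        )
                        outcome = run_imputer(converted[scale], run_spec)
                        records.append(
                            score_imputation(
                                masked,
                                outcome,
                                dataset=ref.name,
                                method=spec.method,
                                repetition=rep,
                                status=ref.status,
                            )
                        )
                    except Exception:
                        logger.exception(
                            "task failed: cohort=%s mech=%s scale=%s method=%s rep=%d",
                            ref.name,
                            mech,
                            scale,
                            spec.method,
                            rep,
                        )
                        n_failed += 1

    scores_df, bins_df = _records_to_frames(records)
    scores_df = scores_df.sort_values(
        ["dataset", "mechanism", "scale", "method", "repetition"], kind="stable"
    ).reset_index(drop=True)
    scores_df.to_csv(scores_path, index=False)
    bins_df.to_csv(bins_path, index=False)

    if records:
        profile_by_range(records).to_csv(outdir / "profile.csv", index=False)
        reports = summarize_table(records, alpha=cfg.alpha)
        cmpdir = outdir / "comparison"
        cmpdir.mkdir(exist_ok=True)
        summary_rows = []
        text_blocks = []
        for rep_ in reports:
            tag = "_".join(map(str, rep_.stratum)) + f"_{rep_.metric}"
            (cmpdir / f"{tag}.json").write_text(rep_.to_json())
            text_blocks.append(render_report(rep_))
            for (method, scale), (mu, sd) in sorted(rep_.summary.items()):
                summary_rows.append(
                    dict(
                        stratum="/".join(map(str, rep_.stratum)),
                        metric=rep_.metric,
                        method=method,
                        scale=scale,
                        mean=mu,
                        sd=sd,
                        scale_winner=rep_.intra_winners.get(method, ""),
                        best=(method, scale) in rep_.best_set,
                    )
                )
        pd.DataFrame(summary_rows).to_csv(cmpdir / "summary.csv", index=False)
        (cmpdir / "tables.txt").write_text("\n\n".join(text_blocks) + "\n")

    meta_path.write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash(),
                "n_records": len(records),
                "n_failed": n_failed,
                "runs_per_dataset_per_method": len(cfg.mechanisms)
                * len(cfg.scales)
                * cfg.repetitions,
            },
            indent=2,
        )
    )
    return records
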