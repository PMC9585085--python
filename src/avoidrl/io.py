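"""Readers, writers and pipeline configuration.

Canonical CSV dialect: comma-separated, UTF-8, header row, "." decimal.
Floats are written at 6 significant digits except log-likelihoods at 10.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import FIT_TABLE_COLUMNS, FitOptions, PriorSpec
from .models import ModelParams
from .task import (
    AgentSpec,
    DEFAULT_POPULATION,
    ParticipantDataset,
    PopulationSpec,
    RatingModelSpec,
    TaskConfig,
)

__all__ = [
    "PipelineConfig",
    "cohort_to_frame",
    "cohort_from_frame",
    "write_trials_csv",
    "read_trials_csv",
    "write_ratings_csv",
    "read_ratings_csv",
    "write_fit_table",
    "read_fit_table",
    "write_manifest",
]

TRIAL_CSV_COLUMNS = [
    "subject_id", "strategy_group", "trial_index", "block_index",
    "within_block_index", "optimal_side", "choice_side", "valid", "rt_ms",
    "feedback", "hit",
]

RATING_CSV_COLUMNS = ["subject_id", "pair_id", "scenario", "rating"]


def _fmt(x, sig=6):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return f"{x:.{sig}g}"


def cohort_to_frame(cohort: Sequence[ParticipantDataset]) -> pd.DataFrame:
    """Stack a cohort into one tidy trial frame (with a ``hit`` column)."""
    frames = []
    for ds in cohort:
        df = ds.trials.copy()
        df.insert(0, "subject_id", ds.subject_id)
        df.insert(1, "strategy_group", ds.strategy_group or "")
        hit = np.where(
            df["valid"].to_numpy(dtype=bool),
            (df["choice_side"] == df["optimal_side"]).astype(int).astype(object),
            "",
        )
        df["hit"] = hit
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[TRIAL_CSV_COLUMNS]


def cohort_from_frame(df: pd.DataFrame) -> List[ParticipantDataset]:
    """Split a tidy trial frame back into per-subject datasets."""
    required = [c for c in TRIAL_CSV_COLUMNS if c != "hit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    cohort = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("trial_index").reset_index(drop=True)
        group = sub["strategy_group"].iloc[0]
        trials = sub[["trial_index", "block_index", "within_block_index",
                      "optimal_side", "choice_side", "valid", "rt_ms",
                      "feedback"]].copy()
        trials["choice_side"] = trials["choice_side"].fillna("")
        trials["valid"] = trials["valid"].astype(bool)
        cohort.append(ParticipantDataset(
            subject_id=str(sid), trials=trials,
            strategy_group=(str(group) if group not in ("", None) and not pd.isna(group) else None),
        ))
    return cohort


def write_trials_csv(cohort: Sequence[ParticipantDataset], path) -> None:
    df = cohort_to_frame(cohort).copy()
    df["rt_ms"] = df["rt_ms"].map(lambda v: _fmt(v))
    df.to_csv(path, index=False)


def read_trials_csv(path) -> List[ParticipantDataset]:
    """Read a trial CSV, validating the schema and naming malformed cells."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[],
                     dtype={"subject_id": str, "choice_side": str,
                            "feedback": str, "strategy_group": str})
    required = [c for c in TRIAL_CSV_COLUMNS if c != "hit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path}: missing required columns {missing}")
    for col in ("trial_index", "block_index", "within_block_index"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as e:
            raise ValueError(f"trial CSV {path}: non-integer value in column {col!r}") from e
    df["rt_ms"] = pd.to_numeric(df["rt_ms"].replace("", np.nan), errors="coerce")
    vmap = {"true": True, "false": False, "1": True, "0": False}
    df["valid"] = df["valid"].astype(str).str.lower().map(vmap)
    if df["valid"].isna().any():
        row = int(df.index[df["valid"].isna()][0])
        raise ValueError(f"trial CSV {path}: unparseable boolean in column 'valid', row {row}")
    bad = ~df["feedback"].isin(["avoidance", "approach", "none", ""])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"trial CSV {path}: bad feedback value in row {row}")
    df.loc[df["feedback"] == "", "feedback"] = "none"
    return cohort_from_frame(df)


def write_ratings_csv(ratings: pd.DataFrame, path) -> None:
    df = ratings[RATING_CSV_COLUMNS].copy()
    df["rating"] = df["rating"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False)


def read_ratings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "scenario": str})
    missing = [c for c in RATING_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rating CSV {path}: missing required columns {missing}")
    return df


def write_fit_table(fit_table: pd.DataFrame, path) -> None:
    df = fit_table.copy()
    for col in ("alpha", "alpha_hab", "beta", "w"):
        df[col] = df[col].map(lambda v: _fmt(v, 6))
    for col in ("ll", "penalized_nll"):
        df[col] = df[col].map(lambda v: _fmt(v, 10))
    df.to_csv(path, index=False)


def read_fit_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "model": str})
    missing = [c for c in ("subject_id", "model", "ll") if c not in df.columns]
    if missing:
        raise ValueError(f"fit table {path}: missing required columns {missing}")
    return df


@dataclass
class PipelineConfig:
    """Seeded end-to-end pipeline settings; round-trips through YAML."""

    seed: int = 0
    n_subjects: int = 214
    task: TaskConfig = field(default_factory=TaskConfig)
    population: PopulationSpec = field(default_factory=lambda: DEFAULT_POPULATION)
    ratings: RatingModelSpec = field(default_factory=RatingModelSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    fit_options: FitOptions = field(default_factory=FitOptions)
    models: tuple = ("simple", "counterfactual")
    n_reps: int = 100

    def to_dict(self) -> dict:
        pop = {
            "groups": {
                name: {
                    "kind": spec.kind,
                    "params": dataclasses.asdict(spec.params) if spec.params else None,
                    "side": spec.side,
                }
                for name, spec in self.population.groups.items()
            },
            "weights": dict(self.population.weights),
        }
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "task": {
                "block_lengths": list(self.task.block_lengths),
                "p_avoid_optimal": self.task.p_avoid_optimal,
                "p_avoid_nonoptimal": self.task.p_avoid_nonoptimal,
                "miss_probability": self.task.miss_probability,
                "anticipation_probability": self.task.anticipation_probability,
            },
            "population": pop,
            "ratings": dataclasses.asdict(self.ratings),
            "priors": dataclasses.asdict(self.priors),
            "fit_options": dataclasses.asdict(self.fit_options),
            "models": list(self.models),
            "n_reps": self.n_reps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        task = TaskConfig(
            block_lengths=tuple(d["task"]["block_lengths"]),
            p_avoid_optimal=d["task"]["p_avoid_optimal"],
            p_avoid_nonoptimal=d["task"]["p_avoid_nonoptimal"],
            miss_probability=d["task"].get("miss_probability", 0.0),
            anticipation_probability=d["task"].get("anticipation_probability", 0.0),
        ) if "task" in d else TaskConfig()
        if "population" in d:
            groups = {}
            for name, g in d["population"]["groups"].items():
                params = ModelParams(**g["params"]) if g.get("params") else None
                groups[name] = AgentSpec(kind=g["kind"], params=params,
                                         side=g.get("side"))
            population = PopulationSpec(groups=groups,
                                        weights=dict(d["population"]["weights"]))
        else:
            population = DEFAULT_POPULATION
        return cls(
            seed=d.get("seed", 0),
            n_subjects=d.get("n_subjects", 214),
            task=task,
            population=population,
            ratings=RatingModelSpec(**d["ratings"]) if "ratings" in d else RatingModelSpec(),
            priors=PriorSpec(**d["priors"]) if "priors" in d else PriorSpec(),
            fit_options=FitOptions(**d["fit_options"]) if "fit_options" in d else FitOptions(),
            models=tuple(d.get("models", ("simple", "counterfactual"))),
            n_reps=d.get("n_reps", 100),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path, seed: int, stage: str, extra: Optional[dict] = None) -> None:
    """Record the seed and package version alongside generated artifacts."""
    from . import __version__

    payload = {"stage": stage, "seed": seed, "avoidrl_version": __version__}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
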