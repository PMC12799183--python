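"""Trial-table serialization, run configuration, and reproducibility plumbing.

Trial data travel as UTF-8 comma-separated text with a header row.  The
schema mirrors the observables of the simulated experiment: subject and
instance identifiers, the 2x2 condition cell, stimulus and choice (1-8),
response time in steps, optional per-strategy continuous confidence columns
(``conf_<strategy>``), and the 1-4 rating (4 = highest confidence).
Unknown columns are preserved on read and round-trip untouched.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import strategies
from .params import (
    DIFFICULTIES,
    N_CLASSES,
    NOISE_SD_EASY,
    NOISE_SD_HARD,
    SATS,
    THRESHOLD_ACCURACY,
    THRESHOLD_SPEED,
    DEFAULT_MEAN_SCALE,
)

REQUIRED_COLUMNS = ("subject_id", "instance_id", "difficulty", "sat",
                    "stimulus", "choice", "rt_steps")


def _validate_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Raise with a row-level diagnostic on the first malformed row.

    Reported line numbers are 1-based file lines (header = line 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    def bad_rows(mask, message):
        if mask.any():
            line = int(df.index[mask][0]) + 2
            raise ValueError(f"{path}, line {line}: {message}")

    bad_rows(~df["difficulty"].isin(DIFFICULTIES),
             f"difficulty must be one of {DIFFICULTIES}")
    bad_rows(~df["sat"].isin(SATS), f"sat must be one of {SATS}")
    for col in ("stimulus", "choice"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_rows(vals.isna() | (vals < 1) | (vals > N_CLASSES) | (vals % 1 != 0),
                 f"{col} must be an integer in 1..{N_CLASSES}")
    rt = pd.to_numeric(df["rt_steps"], errors="coerce")
    bad_rows(rt.isna() | (rt < 1) | (rt % 1 != 0), "rt_steps must be an integer >= 1")
    if "rating" in df.columns:
        rating = pd.to_numeric(df["rating"], errors="coerce")
        bad_rows(rating.isna() | (rating < 1) | (rating > 4) | (rating % 1 != 0),
                 "rating must be an integer in 1..4")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table from CSV."""
    # keep literal strings like the "n/a" instance id out of NaN coercion
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _validate_trials(df, path)
    for col in ("stimulus", "choice", "rt_steps"):
        df[col] = df[col].astype(int)
    if "rating" in df.columns:
        df["rating"] = df["rating"].astype(int)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a trial table as CSV (no index column)."""
    _validate_trials(df, path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat, human-editable configuration of a simulation-and-fitting run."""

    mean_scale: float = DEFAULT_MEAN_SCALE
    noise_sd_easy: float = NOISE_SD_EASY
    noise_sd_hard: float = NOISE_SD_HARD
    threshold_speed: float = THRESHOLD_SPEED
    threshold_accuracy: float = THRESHOLD_ACCURACY
    n_instances: int = 60
    pool_reps: int = 240
    cal_per_class: int = 300
    n_subjects: int = 20
    n_reps: int = 30          # per category per condition cell -> 960 trials
    max_steps: int = 1000
    n_boot: int = 10_000
    seed: int = 0
    generative_strategy: str = "top2diff"
    strategies: tuple[str, ...] = strategies.STRATEGY_NAMES
    output_dir: str = "results"

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(strategies.STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"unknown strategies in config: {sorted(unknown)}")
        self.strategies = tuple(self.strategies)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategies"] = list(self.strategies)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_report(payload: dict, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a JSON report stamped with config hash, seed, and version."""
    from . import __version__

    meta = {"version": __version__,
            "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds")}
    if config is not None:
        meta["config_hash"] = config.config_hash()
        meta["seed"] = config.seed
    doc = {"meta": meta, **payload}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, default=_jsonify))


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def append_log(config: RunConfig, message: str, log_path: str | Path | None = None) -> None:
    """Append a timestamped line carrying the config hash and seed."""
    log_path = Path(log_path or Path(config.output_dir) / "run.log")
    log_path.parent.mkdir(parents=True, exist_ok=True)
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    with open(log_path, "a") as fh:
        fh.write(f"{stamp} config={config.config_hash()} seed={config.seed} {message}\n")
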