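"""Dataset and model file formats plus run configuration.

Datasets travel as comma-separated text with a '.' decimal point: optional
``# key: value`` provenance lines, then a header row naming the score
columns followed by ``label`` (Target/NonTarget) and ``block``.  Floats are
written with shortest round-trip precision, so write -> read -> write is
byte-identical.  Models are single structured JSON text files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import ScoreDataset
from .model import FDMFModel, NONTARGET_LABEL, TARGET_LABEL

__all__ = [
    "RunConfig",
    "write_dataset",
    "read_dataset",
    "save_model",
    "load_model",
]


@dataclass
class RunConfig:
    """Validated configuration shared by the command-line entry points."""

    c: int = 2
    q: float = 2.0
    k1: float = 1.0
    k2: float = 1.0
    grid_step: float = 0.1
    prevalence: float = 0.1
    n_blocks: int = 6
    block_size: int = 3000
    attribute_az: tuple[float, ...] = (0.645, 0.711, 0.616, 0.640, 0.828)
    within_class_corr: float = 0.0
    seed: int = 0
    folds: int = 6
    fuser: str = "fdmf"
    subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if not self.q > 1.0:
            raise ValueError("q must be > 1")
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("k1 and k2 must be > 0")
        if not (0.0 < self.grid_step <= 1.0):
            raise ValueError("grid_step must lie in (0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.fuser not in ("fdmf", "was", "single"):
            raise ValueError("fuser must be one of fdmf, was, single")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def from_sources(cls, config_path: str | None = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file plus keyword overrides.

        Unknown keys in the file are rejected; overrides equal to ``None``
        are ignored so CLI flags only apply when given.
        """
        known = {f.name for f in fields(cls)}
        values: dict = {}
        if config_path is not None:
            loaded = yaml.safe_load(Path(config_path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a key-value mapping")
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config key(s): {sorted(unknown)}")
            values.update(loaded)
        for k, v in overrides.items():
            if v is not None:
                if k not in known:
                    raise ValueError(f"unknown config key {k!r}")
                values[k] = v
        for key in ("attribute_az", "subset"):
            if values.get(key) is not None:
                values[key] = tuple(values[key])
        return cls(**values)


def _format_float(v: float) -> str:
    return repr(float(v))


def write_dataset(path, dataset: ScoreDataset, provenance: dict | None = None) -> None:
    """Write a dataset as provenance-headed CSV."""
    lines: list[str] = []
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}: {v}")
    header = list(dataset.attribute_names) + ["label", "block"]
    lines.append(",".join(header))
    label_names = np.where(dataset.labels == 1, TARGET_LABEL, NONTARGET_LABEL)
    for i in range(dataset.n_samples):
        row = [_format_float(v) for v in dataset.scores[i]]
        row.append(str(label_names[i]))
        row.append(str(int(dataset.block_id[i])))
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dataset(path) -> tuple[ScoreDataset, dict]:
    """Read a dataset file; returns the dataset and its provenance mapping."""
    text = Path(path).read_text()
    provenance: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                provenance[k.strip()] = v.strip()
            continue
        body_lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), float_precision="round_trip")
    for col in ("label", "block"):
        if col not in df.columns:
            raise ValueError(f"dataset file missing required column {col!r}")
    attr_names = [c for c in df.columns if c not in ("label", "block")]
    bad = set(df["label"].unique()) - {TARGET_LABEL, NONTARGET_LABEL}
    if bad:
        raise ValueError(f"unknown label value(s) {sorted(bad)}")
    labels = (df["label"] == TARGET_LABEL).astype(int).to_numpy()
    ds = ScoreDataset(
        scores=df[attr_names].to_numpy(dtype=float),
        labels=labels,
        block_id=df["block"].to_numpy(dtype=int),
        attribute_names=attr_names,
    )
    return ds, provenance


def save_model(path, model: FDMFModel) -> None:
    Path(path).write_text(model.to_json() + "\n")


def load_model(path) -> FDMFModel:
    return FDMFModel.from_json(Path(path).read_text())
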