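"""Delimited-text readers/writers and run configuration.

All tables are UTF-8 delimited text with a header row; the delimiter is
auto-detected between comma and tab. Writers use pandas' shortest-repr
float formatting, so write-then-read round-trips reproduce every value to
full stored precision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .taxonomy import DEFAULT_RANK_THRESHOLDS, RANKS

logger = logging.getLogger(__name__)

_ISOTOPE_ALIASES = {
    "d13c": "d13c", "δ13c": "d13c", "delta13c": "d13c", "d13c_permil": "d13c",
    "d15n": "d15n", "δ15n": "d15n", "delta15n": "d15n", "d15n_permil": "d15n",
    "sample_id": "sample_id", "sampleid": "sample_id", "sample": "sample_id",
}


class FormatError(ValueError):
    """A table does not satisfy its column or value contract."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_isotope_table(
    path: str | Path, metadata: pd.DataFrame | str | Path | None = None
) -> pd.DataFrame:
    """Read per-sample tracer measurements (d13C, d15N in permil).

    Missing delta cells are preserved as NaN and logged; duplicate sample
    ids and missing required columns raise :class:`FormatError` naming the
    offender. Optional metadata (sample_id keyed) is left-joined on.
    """
    df = _read_delimited(path)
    df.columns = [_ISOTOPE_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    for col in ("sample_id", "d13c", "d15n"):
        if col not in df.columns:
            raise FormatError(f"isotope table {path} is missing required column {col!r}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise FormatError(f"duplicate sample_id in {path}: {list(dupes)}")
    for col in ("d13c", "d15n"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        n_missing = int(df[col].isna().sum())
        if n_missing:
            logger.info("%s: %d records missing %s (retained, flagged)", path, n_missing, col)
    if np.isinf(df[["d13c", "d15n"]].to_numpy()).any():
        raise FormatError(f"non-finite delta values in {path}")
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else _read_delimited(metadata)
        overlap = [c for c in meta.columns if c != "sample_id" and c in df.columns]
        df = df.merge(meta.drop(columns=overlap), on="sample_id", how="left")
    return df


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a BLAST-tabular-style hit table with marker and lineage columns."""
    df = _read_delimited(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["esv_id", "marker", "pct_identity", "pct_coverage", "evalue"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"hit table {path} is missing required column {col!r}")
    for col in ("pct_identity", "pct_coverage"):
        vals = pd.to_numeric(df[col], errors="raise")
        bad = vals[(vals < 0) | (vals > 100)]
        if not bad.empty:
            raise FormatError(
                f"{path}: {col} outside [0, 100] (e.g. {bad.iloc[0]})"
            )
        df[col] = vals
    ev = pd.to_numeric(df["evalue"], errors="raise")
    if (ev < 0).any():
        raise FormatError(f"{path}: negative e-value")
    df["evalue"] = ev
    return df


def read_detection_matrix(path: str | Path) -> pd.DataFrame:
    """Read a sample x ESV 0/1 matrix (first column = sample_id)."""
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return df.astype(int)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)


@dataclass
class RunConfig:
    """All tunable pipeline settings, one global seed."""

    rng_seed: int = 0
    # mixing model
    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 10
    alpha: float = 1.0
    resid_prior_scale: float = 1.0
    pooling_threshold: float = 0.6
    sd_floor: float = 0.1
    acidification_cutoff: float = -10.0
    # assignment
    e_cutoff: float = 0.001
    rank_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_RANK_THRESHOLDS))
    blocklist: tuple = ("Homo sapiens",)
    # community
    rank: str = "order"
    distance: str = "jaccard"
    permutations: int = 999
    adjustment: str = "bonferroni"
    # file locations (bundle-relative names or absolute paths)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 <= self.pooling_threshold < 1):
            raise ValueError("pooling_threshold must be in [0, 1)")
        for r, v in self.rank_thresholds.items():
            if r not in RANKS:
                raise ValueError(f"unknown rank {r!r} in thresholds")
            if not (0 < v <= 100):
                raise ValueError(f"threshold for {r} must be in (0, 100]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")

    def stage_rng(self, stage: int) -> np.random.Generator:
        """Independent substream for a stochastic stage."""
        return np.random.default_rng([self.rng_seed, stage])

    def stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence([self.rng_seed, stage]).generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["blocklist"] = list(self.blocklist)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **{k: v for k, v in overrides.items() if v is not None})
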