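"""Stable-isotope data preparation.

Converts raw isotope ratios to delta notation, applies the acidification
quality filter to carbon values, and builds per-source mean/SD summaries
for the mixing model. Sources can later be merged ("pooled") at the level
of raw member samples, which is what the mixing model's iterative
posterior-correlation pooling relies on.

Delta notation expresses an isotope ratio as a per-mil deviation from a
reference standard: delta = 1000 * (R_sample / R_standard - 1). For carbon,
incomplete acidification leaves inorganic carbonate in the sample and drags
d13C far above typical organic-matter values; measurements with d13C above
a cutoff (default -10 permil) are excluded as acidification failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the two tracers, in permil.
TRACERS = ("d13c", "d15n")

#: QC flag set for isotope records.
QC_ACIDIFICATION_FAIL = "acidification_fail"
QC_INSUFFICIENT_MATERIAL = "insufficient_material"


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert an isotope ratio to delta notation (permil).

    Parameters
    ----------
    r_sample : float
        Isotope ratio (e.g. 13C/12C) of the sample; must be >= 0.
    r_standard : float
        Ratio of the reference standard; must be > 0.

    Returns
    -------
    float
        1000 * (r_sample / r_standard - 1), in permil.
    """
    if r_standard <= 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    if r_sample < 0:
        raise ValueError(f"r_sample must be nonnegative, got {r_sample}")
    return 1000.0 * (r_sample / r_standard - 1.0)


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`: recover the sample ratio."""
    if r_standard <= 0:
        raise ValueError(f"r_standard must be positive, got {r_standard}")
    return r_standard * (delta / 1000.0 + 1.0)


def acidification_qc_filter(
    dataset: pd.DataFrame, cutoff: float = -10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records whose d13C exceeds the acidification cutoff.

    Records with d13C strictly greater than ``cutoff`` are flagged
    ``acidification_fail`` and removed; the boundary value itself is kept.
    Records with missing d13C are kept and logged.

    Parameters
    ----------
    dataset : DataFrame
        Isotope records with at least a ``d13c`` column.
    cutoff : float
        Threshold in permil; default -10.

    Returns
    -------
    (kept, removed) : tuple of DataFrame
        Partition of the input. ``removed`` gains the qc flag.
    """
    if "d13c" not in dataset.columns:
        raise KeyError("dataset has no 'd13c' column")
    d13c = dataset["d13c"]
    fail = d13c.notna() & (d13c > cutoff)
    removed = dataset.loc[fail].copy()
    kept = dataset.loc[~fail].copy()
    if not removed.empty:
        removed["qc_flags"] = [
            _add_flag(f, QC_ACIDIFICATION_FAIL)
            for f in removed.get("qc_flags", pd.Series([""] * len(removed), index=removed.index))
        ]
    n_missing = int(d13c.isna().sum())
    logger.info(
        "acidification QC: %d removed (d13C > %g), %d kept, %d with missing d13C retained",
        len(removed), cutoff, len(kept), n_missing,
    )
    return kept, removed


def _add_flag(flags: object, flag: str) -> str:
    existing = "" if flags is None or (isinstance(flags, float) and np.isnan(flags)) else str(flags)
    parts = [p for p in existing.split(";") if p]
    if flag not in parts:
        parts.append(flag)
    return ";".join(parts)


@dataclass
class SourceSummary:
    """Per-source tracer summary backed by its raw member measurements.

    Attributes
    ----------
    name : str
        Source label (e.g. "algae", "BCM", "sediment trap").
    samples : DataFrame
        Raw member rows: ``sample_id`` plus one column per tracer (permil).
        Kept so pooled summaries can be recomputed from raw values.
    sd_floor : float
        SD substituted when a source has a single member (sample SD is
        undefined at n=1 but the mixing model needs positive variance).
    """

    name: str
    samples: pd.DataFrame
    sd_floor: float = 0.1
    tracers: Sequence[str] = TRACERS

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def member_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def mean(self, tracer: str) -> float:
        return float(self.samples[tracer].mean())

    def sd(self, tracer: str) -> float:
        """Sample SD (n-1 denominator); the configured floor when n = 1."""
        if self.n < 2:
            return self.sd_floor
        return float(self.samples[tracer].std(ddof=1))

    def to_row(self) -> dict:
        row: dict = {"source": self.name, "n": self.n}
        for t in self.tracers:
            row[f"mean_{t}"] = self.mean(t)
            row[f"sd_{t}"] = self.sd(t)
        return row


def summarize_sources(
    dataset: pd.DataFrame,
    grouping: Mapping[str, Iterable[str]],
    tracers: Sequence[str] = TRACERS,
    sd_floor: float = 0.1,
) -> list[SourceSummary]:
    """Build per-source summaries from QC-passing samples.

    Parameters
    ----------
    dataset : DataFrame
        Isotope records with ``sample_id`` and tracer columns.
    grouping : mapping of source name -> iterable of sample_ids
        Must partition: a sample id may belong to at most one source.
    tracers : sequence of str
        Tracer columns to summarize; every member sample must have all of
        them present (records missing a tracer are unusable and skipped
        with a log line).
    sd_floor : float
        SD reported for single-member sources.

    Returns
    -------
    list of SourceSummary, in grouping order.
    """
    seen: dict[str, str] = {}
    for name, ids in grouping.items():
        for sid in ids:
            if sid in seen:
                raise ValueError(
                    f"sample {sid!r} assigned to both {seen[sid]!r} and {name!r}; "
                    "grouping must partition"
                )
            seen[sid] = name

    by_id = dataset.set_index("sample_id", drop=False)
    summaries = []
    for name, ids in grouping.items():
        ids = list(ids)
        missing = [s for s in ids if s not in by_id.index]
        if missing:
            raise KeyError(f"source {name!r}: sample ids not in dataset: {missing}")
        rows = by_id.loc[ids]
        usable = rows.dropna(subset=list(tracers))
        n_skip = len(rows) - len(usable)
        if n_skip:
            logger.info("source %s: %d samples skipped (missing tracer values)", name, n_skip)
        if usable.empty:
            raise ValueError(f"source {name!r} has no usable samples (both tracers required)")
        cols = ["sample_id", *tracers]
        summaries.append(
            SourceSummary(name=name, samples=usable[cols].reset_index(drop=True),
                          sd_floor=sd_floor, tracers=tuple(tracers))
        )
    return summaries


def pool_source_samples(
    summaries: Sequence[SourceSummary],
    names: Sequence[str],
    merged_name: str,
) -> SourceSummary:
    """Merge named sources into one, recomputing from raw member samples.

    The merged mean and SD are computed over the union of the member
    measurements, never by averaging the input summaries, so pooling is
    exactly equivalent to relabelling the raw dataset and re-summarizing.
    """
    if len(names) < 2:
        raise ValueError("need at least two sources to pool")
    by_name = {s.name: s for s in summaries}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise KeyError(f"unknown source name(s): {unknown}")
    members = [by_name[n] for n in names]
    merged = pd.concat([m.samples for m in members], ignore_index=True)
    return SourceSummary(
        name=merged_name,
        samples=merged,
        sd_floor=members[0].sd_floor,
        tracers=members[0].tracers,
    )


def summaries_to_frame(summaries: Sequence[SourceSummary]) -> pd.DataFrame:
    """Tabulate summaries (source, n, mean/SD per tracer) for export."""
    return pd.DataFrame([s.to_row() for s in summaries])
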