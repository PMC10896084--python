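"""Rank-thresholded taxonomic assignment of eDNA sequence variants.

Each exact sequence variant (ESV) comes with a set of database hits per
marker (COI, 18S, 16S), each hit carrying a candidate lineage, a percent
identity, a percent query coverage and an e-value. An ESV is assigned at a
taxonomic rank when the best-scoring consistent hit naming a taxon at that
rank reaches the rank's minimum similarity score, where the score is the
product of percent identity and percent query coverage (so a perfect-
coverage 96%-identity hit scores 96). Deeper ranks demand higher scores;
a failure at one rank truncates all deeper ranks, and a tie between
distinct names leaves the rank (and everything below it) undefined.

Decontamination follows standard negative-control screening: an ESV seen
in a batch's blank is struck from every sample of that batch. A taxon
blocklist (humans and other common contaminants) removes ESVs whose
assignment matches a blocked name at any rank.

Score comparisons use exact decimal arithmetic so that two-decimal inputs
sitting exactly on a threshold are never misclassified by float rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: Minimum similarity score (identity x coverage, percent) per rank.
DEFAULT_RANK_THRESHOLDS = {
    "phylum": 85.0,
    "class": 90.0,
    "order": 90.0,
    "family": 95.0,
    "genus": 98.0,
    "species": 99.0,
}

DEFAULT_BLOCKLIST = ("Homo sapiens",)

MARKERS = ("COI", "18S", "16S")


@dataclass(frozen=True)
class RankThresholds:
    """Per-rank minimum assignment scores; must not decrease with depth."""

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.thresholds]
        if missing:
            raise ValueError(f"thresholds missing ranks: {missing}")
        values = [self.thresholds[r] for r in RANKS]
        if any(not (0 < v <= 100) for v in values):
            raise ValueError("thresholds must lie in (0, 100]")
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError("thresholds must be non-decreasing from phylum to species")

    def __getitem__(self, rank: str) -> float:
        return self.thresholds[rank]


def _exact(x: float | int | str | Decimal) -> Decimal:
    """Decimal view of a numeric input, exact for decimal-string inputs."""
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


def similarity_score(identity: float, coverage: float) -> float:
    """Sequence similarity score: percent identity x percent coverage / 100."""
    if not (0 <= identity <= 100):
        raise ValueError(f"identity out of [0, 100]: {identity}")
    if not (0 <= coverage <= 100):
        raise ValueError(f"coverage out of [0, 100]: {coverage}")
    return float(_exact(identity) * _exact(coverage) / 100)


def _score_exact(identity, coverage) -> Decimal:
    return _exact(identity) * _exact(coverage) / 100


def filter_hits(table: pd.DataFrame, e_cutoff: float = 0.001) -> pd.DataFrame:
    """Keep hits with e-value <= cutoff (inclusive, BLAST convention)."""
    keep = table["evalue"] <= e_cutoff
    removed = table.loc[~keep]
    if not removed.empty:
        per_esv = removed.groupby("esv_id").size()
        logger.info(
            "e-value filter (cutoff %g): removed %d hits across %d ESVs",
            e_cutoff, len(removed), len(per_esv),
        )
    return table.loc[keep].reset_index(drop=True)


@dataclass
class RankAssignment:
    """Per-rank assignment for one ESV (optionally one marker)."""

    esv_id: str
    assigned: dict[str, str | None]
    best_score: dict[str, float | None]
    markers: tuple[str, ...] = ()

    @property
    def depth(self) -> str | None:
        """Deepest assigned rank, or None if nothing was assigned."""
        deepest = None
        for r in RANKS:
            if self.assigned.get(r) is not None:
                deepest = r
        return deepest

    def lineage(self) -> tuple[str | None, ...]:
        return tuple(self.assigned.get(r) for r in RANKS)


def assign_ranks(
    hits: pd.DataFrame,
    thresholds: RankThresholds | Mapping[str, float] = None,
) -> RankAssignment:
    """Assign taxonomy to one ESV(+marker) from its e-value-filtered hits.

    Walking from phylum to species: among hits that name a taxon at the
    rank and agree with every shallower assignment, the top-scoring name is
    assigned iff its score meets the rank threshold and no distinct name
    ties it; the first failing rank leaves that rank and all deeper ranks
    undefined.
    """
    if thresholds is None:
        thresholds = RankThresholds()
    elif not isinstance(thresholds, RankThresholds):
        thresholds = RankThresholds(dict(thresholds))
    if hits.empty:
        return RankAssignment("", {r: None for r in RANKS}, {r: None for r in RANKS})
    esv_ids = hits["esv_id"].unique()
    if len(esv_ids) != 1:
        raise ValueError(f"assign_ranks expects hits for one ESV, got {list(esv_ids)}")
    markers = tuple(sorted(hits["marker"].unique())) if "marker" in hits.columns else ()

    scores = [
        _score_exact(i, c)
        for i, c in zip(hits["pct_identity"], hits["pct_coverage"])
    ]
    assigned: dict[str, str | None] = {r: None for r in RANKS}
    best_score: dict[str, float | None] = {r: None for r in RANKS}
    parent: dict[str, str] = {}
    truncated = False
    for rank in RANKS:
        if truncated:
            break
        best: Decimal | None = None
        names: set[str] = set()
        for (_, hit), score in zip(hits.iterrows(), scores):
            name = hit.get(rank)
            if name is None or (isinstance(name, float) and np.isnan(name)) or name == "":
                continue
            # consistency with shallower assignments
            ok = True
            for pr, pname in parent.items():
                hv = hit.get(pr)
                if hv is None or (isinstance(hv, float) and np.isnan(hv)) or hv != pname:
                    ok = False
                    break
            if not ok:
                continue
            if best is None or score > best:
                best, names = score, {str(name)}
            elif score == best:
                names.add(str(name))
        if best is None:
            truncated = True
            continue
        best_score[rank] = float(best)
        if len(names) > 1 or best < _exact(thresholds[rank]):
            truncated = True
            continue
        (name,) = names
        assigned[rank] = name
        parent[rank] = name
    return RankAssignment(str(esv_ids[0]), assigned, best_score, markers)


def assign_hit_table(
    table: pd.DataFrame,
    thresholds: RankThresholds | Mapping[str, float] = None,
    e_cutoff: float = 0.001,
) -> list[RankAssignment]:
    """E-value-filter a hit table and assign every (ESV, marker) group."""
    filtered = filter_hits(table, e_cutoff)
    out = []
    for (_esv, _marker), grp in filtered.groupby(["esv_id", "marker"], sort=True):
        out.append(assign_ranks(grp, thresholds))
    return out


def assignments_to_frame(assignments: Iterable[RankAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        row = {"esv_id": a.esv_id, "markers": ";".join(a.markers)}
        for r in RANKS:
            row[r] = a.assigned.get(r)
            row[f"score_{r}"] = a.best_score.get(r)
        rows.append(row)
    return pd.DataFrame(rows)


def remove_negative_control_esvs(
    detections: pd.DataFrame,
    negative_ids: Sequence[str],
    batch_map: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a sample x ESV detection matrix against negative controls.

    Any ESV detected in a batch's negative control is removed from every
    sample of that batch; the negative-control rows themselves are dropped
    from the returned matrix.

    Returns
    -------
    (cleaned, removal_log)
        ``cleaned``: detection matrix without negative rows and with
        contaminated cells zeroed. ``removal_log``: one row per (batch,
        esv) removal with the count of affected samples.
    """
    missing = [s for s in detections.index if s not in batch_map]
    if missing:
        raise KeyError(f"samples without a batch assignment: {missing}")
    unknown_neg = [s for s in negative_ids if s not in detections.index]
    if unknown_neg:
        raise KeyError(f"negative-control ids not in detection matrix: {unknown_neg}")

    cleaned = detections.drop(index=list(negative_ids)).copy()
    log_rows = []
    for neg in negative_ids:
        batch = batch_map[neg]
        flagged = detections.columns[detections.loc[neg] > 0]
        batch_samples = [s for s in cleaned.index if batch_map[s] == batch]
        for esv in flagged:
            n_hit = int((cleaned.loc[batch_samples, esv] > 0).sum())
            cleaned.loc[batch_samples, esv] = 0
            log_rows.append(
                {"batch": batch, "negative": neg, "esv_id": esv, "samples_affected": n_hit}
            )
    log = pd.DataFrame(log_rows, columns=["batch", "negative", "esv_id", "samples_affected"])
    logger.info(
        "negative-control screen: %d ESV/batch removals affecting %d detections",
        len(log), int(log["samples_affected"].sum()) if not log.empty else 0,
    )
    return cleaned, log


def apply_taxon_blocklist(
    table: pd.DataFrame,
    blocklist: Sequence[str] = DEFAULT_BLOCKLIST,
) -> pd.DataFrame:
    """Drop rows whose assignment matches a blocked name at any rank.

    A genus-level blocklist entry therefore removes every species under
    that genus, since the genus name is present in the row's lineage.
    """
    if not blocklist:
        return table.copy()
    blocked = set(blocklist)
    rank_cols = [r for r in RANKS if r in table.columns]
    mask = table[rank_cols].isin(blocked).any(axis=1)
    if mask.any():
        logger.info("blocklist removed %d of %d rows", int(mask.sum()), len(table))
    return table.loc[~mask].reset_index(drop=True)


def verify_names(
    table: pd.DataFrame,
    validated_names: Iterable[str],
    strict: bool = False,
) -> pd.DataFrame:
    """Flag assigned names against an offline validated-name list.

    Adds ``unverified_names`` (semicolon list of assigned names absent from
    the list) and boolean ``verified``. In strict mode rows with any
    unverified name are dropped and logged.
    """
    valid = set(validated_names)
    rank_cols = [r for r in RANKS if r in table.columns]
    out = table.copy()
    unverified = []
    for _, row in out.iterrows():
        bad = [
            str(row[r]) for r in rank_cols
            if pd.notna(row[r]) and row[r] != "" and str(row[r]) not in valid
        ]
        unverified.append(";".join(bad))
    out["unverified_names"] = unverified
    out["verified"] = [u == "" for u in unverified]
    if strict:
        dropped = int((~out["verified"]).sum())
        if dropped:
            logger.info("strict name verification dropped %d of %d rows", dropped, len(out))
        out = out.loc[out["verified"]].reset_index(drop=True)
    return out


def consolidate_markers(
    assignments_by_marker: Mapping[str, Iterable[RankAssignment]],
    detections_by_marker: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Union per-marker assignments into a per-sample taxonomy table.

    A taxon is "detected" in a sample if any marker's ESV detected in that
    sample assigns to it. Rows are (sample_id, lineage...) with a
    ``markers`` provenance column; identical lineages found by several
    markers collapse to one row carrying all markers.
    """
    acc: dict[tuple, set[str]] = {}
    for marker, assignments in assignments_by_marker.items():
        det = detections_by_marker[marker]
        by_esv = {a.esv_id: a for a in assignments}
        for esv in det.columns:
            a = by_esv.get(esv)
            if a is None or a.depth is None:
                continue
            lineage = a.lineage()
            for sample in det.index[det[esv] > 0]:
                key = (sample, lineage)
                acc.setdefault(key, set()).add(marker)
    rows = []
    for (sample, lineage), markers in sorted(
        acc.items(), key=lambda kv: (kv[0][0], tuple(x or "" for x in kv[0][1]))
    ):
        row = {"sample_id": sample}
        row.update(dict(zip(RANKS, lineage)))
        row["markers"] = ";".join(sorted(markers))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *RANKS, "markers"])
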