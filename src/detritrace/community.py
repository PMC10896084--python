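"""Presence/absence community comparison for metabarcoding detections.

Builds sample x taxon presence/absence matrices at a chosen taxonomic
rank, computes frequency-of-occurrence summaries, and compares groups of
samples with permutation statistics: PERMANOVA (pseudo-F on a distance
matrix, whole-row label permutation), pairwise PERMANOVA with multiple-
testing adjustment, SIMPER (per-taxon percentage contributions to the
mean between-group Bray-Curtis dissimilarity) and non-metric
multidimensional scaling (NMDS) ordination.

The PERMANOVA pseudo-F uses the classical partition of squared
inter-point distances (equivalent to the Gower-centered inner-product
decomposition):

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_groups (1/n_g) sum_{i<j in g} d_ij^2
    F = (SS_between / (a - 1)) / (SS_within / (N - a))

with p = (1 + #{F_perm >= F_obs}) / (1 + permutations) under random
relabelling, or an exhaustive enumeration of all label orderings when
requested.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .taxonomy import RANKS

logger = logging.getLogger(__name__)


@dataclass
class CommunityMatrix:
    """Sample x taxon presence/absence matrix with per-sample group labels."""

    data: pd.DataFrame          # 0/1 ints, index = sample_id, columns = taxa
    groups: pd.Series           # group label per sample, same index
    rank: str = "order"
    lineage: pd.DataFrame | None = None  # per-taxon parent ranks, for roll-ups

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("community matrix entries must be 0/1")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate taxa columns")
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")


@dataclass(frozen=True)
class FrequencyResult:
    taxon: str
    sample_type: str
    numerator: int
    denominator: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def percent_rounded(self) -> int:
        return round(self.percent)


def frequency_of_occurrence(
    taxonomy_table: pd.DataFrame,
    metadata: pd.DataFrame,
    sample_type: str,
    taxon: str,
    rank: str | None = None,
) -> FrequencyResult:
    """Share of a sample type's samples in which a taxon was detected.

    The denominator is the number of sequenced samples of that type in the
    metadata (not only those with detections); the numerator counts samples
    whose consolidated taxonomy contains ``taxon`` at ``rank`` (any rank if
    omitted).
    """
    of_type = metadata.loc[metadata["sample_type"] == sample_type, "sample_id"]
    if of_type.empty:
        raise ValueError(f"no samples of type {sample_type!r} in metadata")
    ranks = [rank] if rank else [r for r in RANKS if r in taxonomy_table.columns]
    if rank and rank not in taxonomy_table.columns:
        raise ValueError(f"unknown rank {rank!r}")
    hit = taxonomy_table[ranks].eq(taxon).any(axis=1)
    positive = set(taxonomy_table.loc[hit, "sample_id"])
    num = int(sum(s in positive for s in of_type))
    return FrequencyResult(taxon, sample_type, num, len(of_type))


def frequency_table(
    taxonomy_table: pd.DataFrame,
    metadata: pd.DataFrame,
    rank: str,
) -> pd.DataFrame:
    """Frequency of occurrence of every rank-level taxon per sample type."""
    taxa = sorted(taxonomy_table[rank].dropna().unique())
    types = sorted(metadata["sample_type"].unique())
    rows = []
    for taxon in taxa:
        row: dict = {"taxon": taxon, "rank": rank}
        for t in types:
            f = frequency_of_occurrence(taxonomy_table, metadata, t, taxon, rank)
            row[f"pct_{t}"] = f.percent_rounded
        rows.append(row)
    return pd.DataFrame(rows)


def collapse_to_rank(
    taxonomy_table: pd.DataFrame,
    rank: str,
    groups: Mapping[str, str] | pd.Series,
) -> CommunityMatrix:
    """Binary sample x taxon matrix at the requested rank.

    Detections unassigned at that rank are excluded (and counted in the
    log). Samples are the keys of ``groups``; a sample with no assigned
    detection at the rank keeps an all-zero row.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    table = taxonomy_table.loc[taxonomy_table["sample_id"].isin(groups.index)]
    assigned = table[rank].notna() & (table[rank] != "")
    n_excluded = int((~assigned).sum())
    if n_excluded:
        logger.info("collapse to %s: %d detections unassigned at that rank excluded",
                    rank, n_excluded)
    sub = table.loc[assigned]
    taxa = sorted(sub[rank].unique())
    data = pd.DataFrame(0, index=list(groups.index), columns=taxa, dtype=int)
    for _, row in sub.iterrows():
        data.loc[row["sample_id"], row[rank]] = 1
    # parent lineage of each rank-level taxon, for roll-ups (e.g. SIMPER
    # contributions aggregated to phylum)
    above = [r for r in RANKS[: RANKS.index(rank)]]
    lineage = None
    if above:
        lineage = (
            sub[[*above, rank]].drop_duplicates(subset=[rank]).set_index(rank).loc[taxa]
        )
    return CommunityMatrix(data=data, groups=groups, rank=rank, lineage=lineage)


def jaccard_distance_matrix(m: CommunityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances, d = 1 - |A & B| / |A | B|."""
    data = m.data if isinstance(m, CommunityMatrix) else m
    zero = data.sum(axis=1) == 0
    if zero.any():
        raise ValueError(
            f"all-zero presence rows (no detections): {list(data.index[zero])}"
        )
    d = pdist(data.to_numpy(bool), metric="jaccard")
    return pd.DataFrame(squareform(d), index=data.index, columns=data.index)


@dataclass(frozen=True)
class PermanovaResult:
    f: float
    df_among: int
    df_resid: int
    p: float
    permutations: int
    seed: int | None

    def __str__(self) -> str:
        return (
            f"PERMANOVA F_{self.df_among},{self.df_resid} = {self.f:.4f}, "
            f"p = {self.p:.3g} ({self.permutations} permutations)"
        )


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, codes: np.ndarray) -> float:
    """Pseudo-F from squared distances for integer-coded labels."""
    n = d2.shape[0]
    a = len(codes)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in codes:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: pd.DataFrame | np.ndarray,
    groups: Sequence[str] | pd.Series,
    permutations: int = 999,
    seed: int | None = None,
    method: str = "monte-carlo",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``method="exact"`` enumerates every ordering of the labels (feasible
    for small N) and reports p as the fraction of orderings with
    F >= F_obs; otherwise ``permutations`` random whole-row relabellings
    are drawn and p = (1 + #{F_perm >= F_obs}) / (1 + permutations).
    """
    dm = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if isinstance(groups, pd.Series) and isinstance(d, pd.DataFrame):
        groups = groups.reindex(d.index)
    labels, codes = pd.factorize(np.asarray(groups))
    n = dm.shape[0]
    if len(labels) != n:
        raise ValueError("groups length must match distance matrix")
    if len(codes) < 2:
        raise ValueError("need at least two groups")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    d2 = dm**2
    codes_idx = np.arange(len(codes))
    f_obs = _pseudo_f(d2, labels, codes_idx)
    tol = 1e-12

    if method == "exact":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            f_p = _pseudo_f(d2, labels[list(perm)], codes_idx)
            count += f_p >= f_obs - tol
            total += 1
        p = count / total
        permutations = total
    elif method == "monte-carlo":
        rng = np.random.default_rng(seed)
        count = 0
        lab = labels.copy()
        for _ in range(permutations):
            rng.shuffle(lab)
            count += _pseudo_f(d2, lab, codes_idx) >= f_obs - tol
        p = (1 + count) / (1 + permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(
        f=f_obs,
        df_among=len(codes) - 1,
        df_resid=n - len(codes),
        p=p,
        permutations=permutations,
        seed=seed,
    )


def adjust_pvalues(p: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Multiple-testing adjustment across pairwise tests."""
    p = list(p)
    m = len(p)
    if method == "none":
        return p
    if method == "bonferroni":
        return [min(1.0, v * m) for v in p]
    if method == "holm":
        order = np.argsort(p)
        out = [0.0] * m
        running = 0.0
        for i, idx in enumerate(order):
            running = max(running, min(1.0, (m - i) * p[idx]))
            out[idx] = running
        return out
    raise ValueError(f"unknown adjustment {method!r}")


def pairwise_permanova(
    d: pd.DataFrame,
    groups: pd.Series,
    permutations: int = 999,
    adjustment: str = "bonferroni",
    seed: int | None = None,
) -> pd.DataFrame:
    """One PERMANOVA per group pair on the pair's distance sub-matrix."""
    groups = groups.reindex(d.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, (ga, gb) in enumerate(itertools.combinations(levels, 2)):
        idx = groups.index[groups.isin([ga, gb])]
        sub = d.loc[idx, idx]
        pair_seed = None if seed is None else seed + i
        res = permanova(sub, groups.loc[idx], permutations, seed=pair_seed)
        rows.append({"group_a": ga, "group_b": gb, "f": res.f, "p_raw": res.p,
                     "permutations": res.permutations})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_raw"], adjustment)
    out["adjustment"] = adjustment
    return out


def simper(
    m: CommunityMatrix,
    group_a: str,
    group_b: str,
    rollup_rank: str | None = None,
) -> pd.DataFrame:
    """Per-taxon contribution to mean between-group Bray-Curtis dissimilarity.

    For presence/absence data Bray-Curtis between samples x, y decomposes
    per taxon t as |x_t - y_t| / sum_t (x_t + y_t); contributions are the
    average of these terms over all cross-group pairs, expressed as a
    percentage of the mean dissimilarity (so they sum to 100). With
    ``rollup_rank`` the taxon contributions are summed up to that higher
    rank using the matrix's lineage table.
    """
    ia = m.groups.index[m.groups == group_a]
    ib = m.groups.index[m.groups == group_b]
    if ia.empty or ib.empty:
        raise ValueError(f"empty group: {group_a if ia.empty else group_b!r}")
    X = m.data.loc[ia].to_numpy(float)
    Y = m.data.loc[ib].to_numpy(float)
    taxa = list(m.data.columns)
    terms = np.zeros(len(taxa))
    n_pairs = 0
    for x in X:
        for y in Y:
            tot = (x + y).sum()
            if tot == 0:
                continue
            terms += np.abs(x - y) / tot
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no usable cross-group pairs (all rows empty)")
    mean_terms = terms / n_pairs
    out = pd.DataFrame({"taxon": taxa, "rank": m.rank, "contribution": mean_terms})
    if rollup_rank is not None:
        if m.lineage is None or rollup_rank not in m.lineage.columns:
            raise ValueError(f"no lineage information to roll up to {rollup_rank!r}")
        out["taxon"] = [m.lineage.loc[t, rollup_rank] for t in taxa]
        out["rank"] = rollup_rank
        out = out.groupby(["taxon", "rank"], as_index=False)["contribution"].sum()
    total = out["contribution"].sum()
    out["percent"] = 0.0 if total == 0 else 100.0 * out["contribution"] / total
    out["mean_dissimilarity"] = total
    return out.sort_values("percent", ascending=False).reset_index(drop=True)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool = True


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    restarts: int = 4,
    seed: int | None = None,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric multidimensional scaling of a distance matrix.

    SMACOF iterative majorization with isotonic regression on the
    disparities; the best of ``restarts`` random starts is returned with
    its Kruskal stress-1. The configuration is centered at the origin.
    """
    dm = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(dm.shape[0])
    n = dm.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} samples, got {n}")
    off = dm[np.triu_indices(n, k=1)]
    if np.allclose(off, off[0]):
        # All pairs equidistant: every monotone transform fits the ties, so
        # any faithful configuration has zero non-metric stress; return the
        # classical-scaling layout.
        warnings.warn("all pairwise distances equal; returning metric layout "
                      "with stress 0", RuntimeWarning, stacklevel=2)
        model = MDS(n_components=k, dissimilarity="precomputed",
                    n_init=restarts, random_state=seed, normalized_stress=False,
                    max_iter=max_iter)
        coords = model.fit_transform(dm)
        coords -= coords.mean(axis=0)
        return NmdsResult(pd.DataFrame(coords, index=index), 0.0)
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=restarts,
        random_state=seed,
        max_iter=max_iter,
        normalized_stress=True,
    )
    coords = model.fit_transform(dm)
    coords -= coords.mean(axis=0)
    cols = [f"nmds{i + 1}" for i in range(k)]
    return NmdsResult(pd.DataFrame(coords, index=index, columns=cols), float(model.stress_))


def group_ellipses(coords: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Standard-error ellipse parameters (center, axes) per group."""
    groups = groups.reindex(coords.index)
    rows = []
    for g, idx in coords.groupby(groups).groups.items():
        pts = coords.loc[idx].to_numpy()
        center = pts.mean(axis=0)
        se = pts.std(axis=0, ddof=1) / np.sqrt(len(pts)) if len(pts) > 1 else np.zeros(pts.shape[1])
        row = {"group": g, "n": len(pts)}
        for i in range(pts.shape[1]):
            row[f"center{i + 1}"] = center[i]
            row[f"se{i + 1}"] = se[i]
        rows.append(row)
    return pd.DataFrame(rows)
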