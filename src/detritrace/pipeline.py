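"""End-to-end pipeline: bundle directory in, report directory out.

A *bundle* is a directory of delimited-text inputs, the shape the
``simulate`` command writes:

    sources.csv           per-sample source isotope measurements
    mixtures.csv          detritus (mixture) isotope measurements
    metadata.csv          sample_id, sample_type, group, season, batch, is_negative
    hits_<marker>.csv     per-ESV hit table per marker
    detections_<marker>.csv  sample x ESV 0/1 matrix per marker
    truth.json            ground truth (written by simulate only)

``run_pipeline`` executes both arms — isotope mixing with pooling, and
eDNA assignment/decontamination/frequency/community — writing result
tables, a pooling trace and a run log into the output directory. A given
seed and bundle always reproduce the same outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as cm
from . import isotopes as iso
from . import mixing as mx
from . import taxonomy as tx
from .io import (
    RunConfig,
    read_detection_matrix,
    read_hit_table,
    read_isotope_table,
    write_table,
)
from .synthetic import (
    EdnaScenario,
    IsotopeScenario,
    generate_edna_dataset,
    generate_isotope_dataset,
    source_grouping,
)

logger = logging.getLogger(__name__)

MARKERS = ("COI", "18S", "16S")

# stage indices for deriving independent random substreams from the one
# configured seed
_STAGE_SIMULATE_ISO = 1
_STAGE_SIMULATE_EDNA = 2
_STAGE_MIXING = 3
_STAGE_COMMUNITY = 4


class StageError(RuntimeError):
    """An error in one pipeline stage, labelled with the stage name."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


def write_bundle(
    bundle_dir: str | Path,
    config: RunConfig,
    isotope_scenario: IsotopeScenario,
    edna_scenario: EdnaScenario,
) -> Path:
    """Simulate both arms and write a bundle directory."""
    out = Path(bundle_dir)
    out.mkdir(parents=True, exist_ok=True)
    sources, mixtures, iso_truth = generate_isotope_dataset(
        isotope_scenario, seed=config.stage_seed(_STAGE_SIMULATE_ISO)
    )
    write_table(sources, out / "sources.csv")
    write_table(mixtures, out / "mixtures.csv")
    edna = generate_edna_dataset(
        edna_scenario, seed=config.stage_seed(_STAGE_SIMULATE_EDNA)
    )
    write_table(edna.metadata, out / "metadata.csv")
    for m, hits in edna.hit_tables.items():
        write_table(hits, out / f"hits_{m}.csv")
    for m, det in edna.detections.items():
        write_table(det.reset_index(names="sample_id"), out / f"detections_{m}.csv")
    truth = {
        "true_p": iso_truth.true_p,
        "contaminant_esvs": edna.truth["contaminant_esvs"],
        "rng_seed": config.rng_seed,
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out


@_stage("sia-fit")
def run_sia(config: RunConfig, bundle: Path, out: Path) -> dict:
    sources = read_isotope_table(bundle / "sources.csv")
    mixtures = read_isotope_table(bundle / "mixtures.csv")
    kept, removed = iso.acidification_qc_filter(sources, config.acidification_cutoff)
    mix_kept, mix_removed = iso.acidification_qc_filter(mixtures, config.acidification_cutoff)
    summaries = iso.summarize_sources(
        kept, source_grouping(kept), sd_floor=config.sd_floor
    )
    write_table(iso.summaries_to_frame(summaries), out / "source_summaries.csv")
    settings = mx.McmcSettings(config.iterations, config.burn_in, config.thin)
    draws, trace = mx.pool_correlated_sources(
        summaries,
        mix_kept[["d13c", "d15n"]].dropna().to_numpy(),
        threshold=config.pooling_threshold,
        settings=settings,
        seed=config.stage_seed(_STAGE_MIXING),
        alpha=config.alpha,
        resid_prior_scale=config.resid_prior_scale,
    )
    summary = mx.posterior_summary(draws)
    write_table(summary, out / "posterior_summary.csv")
    write_table(draws.to_frame(), out / "posterior_draws.csv")
    (out / "pooling_trace.txt").write_text(trace.describe() + "\n", encoding="utf-8")
    logger.info(
        "sia-fit: %d source samples removed by acidification QC, %d mixtures removed",
        len(removed), len(mix_removed),
    )
    return {
        "summary": summary,
        "draws": draws,
        "trace": trace,
        "qc_removed": len(removed) + len(mix_removed),
    }


@_stage("assign")
def run_assign(config: RunConfig, bundle: Path, out: Path) -> dict:
    metadata = pd.read_csv(bundle / "metadata.csv")
    thresholds = tx.RankThresholds(config.rank_thresholds)
    assignments_by_marker: dict[str, list[tx.RankAssignment]] = {}
    detections_by_marker: dict[str, pd.DataFrame] = {}
    negatives = list(metadata.loc[metadata["is_negative"].astype(bool), "sample_id"])
    batch_map = dict(zip(metadata["sample_id"], metadata["batch"]))
    removal_logs = []
    for marker in MARKERS:
        hit_path = bundle / f"hits_{marker}.csv"
        det_path = bundle / f"detections_{marker}.csv"
        if not hit_path.exists():
            raise FileNotFoundError(f"hit table not found: {hit_path}")
        if not det_path.exists():
            raise FileNotFoundError(f"detection matrix not found: {det_path}")
        hits = read_hit_table(hit_path)
        detections = read_detection_matrix(det_path)
        cleaned, removal_log = tx.remove_negative_control_esvs(
            detections, negatives, batch_map
        )
        removal_log.insert(0, "marker", marker)
        removal_logs.append(removal_log)
        assignments = tx.assign_hit_table(hits, thresholds, config.e_cutoff)
        assignments_by_marker[marker] = assignments
        detections_by_marker[marker] = cleaned
    taxonomy_table = tx.consolidate_markers(assignments_by_marker, detections_by_marker)
    taxonomy_table = tx.apply_taxon_blocklist(taxonomy_table, config.blocklist)
    assignment_frames = [
        tx.assignments_to_frame(a) for a in assignments_by_marker.values()
    ]
    write_table(pd.concat(assignment_frames, ignore_index=True), out / "assignments.csv")
    write_table(pd.concat(removal_logs, ignore_index=True), out / "decontamination_log.csv")
    write_table(taxonomy_table, out / "taxonomy_table.csv")
    return {
        "taxonomy_table": taxonomy_table,
        "metadata": metadata,
        "detections": detections_by_marker,
    }


@_stage("frequency")
def run_frequency(config: RunConfig, taxonomy_table: pd.DataFrame,
                  metadata: pd.DataFrame, out: Path) -> dict:
    meta = metadata.loc[~metadata["is_negative"].astype(bool)]
    tables = {}
    for rank in ("phylum", config.rank):
        tab = cm.frequency_table(taxonomy_table, meta, rank)
        write_table(tab, out / f"frequency_{rank}.csv")
        tables[rank] = tab
    return tables


@_stage("community")
def run_community(config: RunConfig, taxonomy_table: pd.DataFrame,
                  metadata: pd.DataFrame, out: Path) -> dict:
    meta = metadata.loc[~metadata["is_negative"].astype(bool)]
    detritus = meta.loc[meta["sample_type"].isin(["EAM", "tray"])]
    groups = pd.Series(detritus["group"].to_numpy(), index=detritus["sample_id"])
    matrix = cm.collapse_to_rank(taxonomy_table, config.rank, groups)
    # drop samples with no assigned detections at this rank (can happen at
    # nonzero dropout); they carry no distance information
    nonzero = matrix.data.sum(axis=1) > 0
    if not nonzero.all():
        logger.info("community: dropped %d sample(s) with no %s-level detections",
                    int((~nonzero).sum()), config.rank)
        matrix = cm.CommunityMatrix(matrix.data.loc[nonzero],
                                    matrix.groups.loc[nonzero],
                                    matrix.rank, matrix.lineage)
    d = cm.jaccard_distance_matrix(matrix)
    write_table(d.reset_index(names="sample_id"), out / "jaccard_distances.csv")
    seed = config.stage_seed(_STAGE_COMMUNITY)
    res = cm.permanova(d, matrix.groups, config.permutations, seed=seed)
    perm_df = pd.DataFrame([{
        "f": res.f, "df_among": res.df_among, "df_resid": res.df_resid,
        "p": res.p, "permutations": res.permutations, "seed": seed,
    }])
    write_table(perm_df, out / "permanova.csv")
    pw = cm.pairwise_permanova(d, matrix.groups, config.permutations,
                               config.adjustment, seed=seed)
    write_table(pw, out / "pairwise_permanova.csv")
    levels = sorted(matrix.groups.unique())
    simp = cm.simper(matrix, levels[0], levels[1],
                     rollup_rank="phylum" if config.rank != "phylum" else None)
    write_table(simp, out / "simper.csv")
    ord_res = cm.nmds(d, k=2, seed=seed)
    write_table(ord_res.coordinates.reset_index(names="sample_id"), out / "nmds_coordinates.csv")
    write_table(cm.group_ellipses(ord_res.coordinates, matrix.groups), out / "nmds_ellipses.csv")
    return {"matrix": matrix, "permanova": res, "pairwise": pw,
            "simper": simp, "nmds": ord_res}


def run_pipeline(config: RunConfig, bundle_dir: str | Path, out_dir: str | Path) -> dict:
    """Run every stage on a bundle; returns the in-memory results."""
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not bundle.exists():
        raise FileNotFoundError(f"bundle directory not found: {bundle}")
    config.to_yaml(out / "config_used.yaml")
    logger.info("run: seed=%d bundle=%s", config.rng_seed, bundle)
    results = {"sia": run_sia(config, bundle, out)}
    assign = run_assign(config, bundle, out)
    results["assign"] = assign
    results["frequency"] = run_frequency(
        config, assign["taxonomy_table"], assign["metadata"], out
    )
    results["community"] = run_community(
        config, assign["taxonomy_table"], assign["metadata"], out
    )
    return results
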