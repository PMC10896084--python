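"""Synthetic datasets with known ground truth for every pipeline stage.

Two generators mirror the two arms of the analysis:

* :func:`generate_isotope_dataset` draws per-source tracer measurements
  from Normal(mu, sigma) and mixture samples from the mixing model's own
  likelihood (mean = convex combination of source means, variance =
  p^2-weighted source variances plus residual), so posterior recovery can
  be scored against the true proportion vector. A ``near_collinear``
  switch duplicates one source with tracer means offset by less than
  0.2 permil, the regime that produces strongly correlated posteriors and
  exercises the pooling loop.

* :func:`generate_edna_dataset` builds multi-marker hit tables and
  sample x ESV detection matrices from a taxon pool with full lineages.
  Hit identity/coverage are drawn inside score bands chosen so each ESV is
  assignable exactly to its taxon's intended rank depth; marker dropout,
  batch-structured negative-control contamination and group-structured
  occurrence probabilities are all controlled, and the truth record keeps
  the exact community so downstream assignment, decontamination,
  frequency and community statistics can be scored without re-reading
  scenario internals.

Sequences themselves are never simulated: the pipeline consumes hit
tables, so identity/coverage bands carry all the test power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import DEFAULT_RANK_THRESHOLDS, RANKS

# --------------------------------------------------------------------------
# isotope arm
# --------------------------------------------------------------------------


@dataclass
class IsotopeScenario:
    """Ground-truth layout for a two-tracer source/mixture simulation."""

    source_names: Sequence[str]
    mu: np.ndarray                      # (K, J) permil
    sigma: np.ndarray                   # (K, J) permil
    n_per_source: Sequence[int]
    true_p: np.ndarray                  # (K,) simplex
    resid_sd: float | Sequence[float] = 0.5
    n_mixtures: int = 10
    #: number of source samples given a carbonate-contaminated d13C (above
    #: the acidification QC cutoff), emulating incomplete acidification
    n_acid_fail: int = 0
    near_collinear: bool = False
    collinear_offset: Sequence[float] = (0.15, -0.10)
    tracers: Sequence[str] = ("d13c", "d15n")

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, float))
        self.true_p = np.asarray(self.true_p, float)
        if np.any(self.sigma < 0):
            raise ValueError("source SDs must be nonnegative")
        if np.any(self.true_p < 0) or abs(self.true_p.sum() - 1.0) > 1e-9:
            raise ValueError("true_p must lie on the simplex")
        if len(self.source_names) != self.mu.shape[0]:
            raise ValueError("source_names must match mu rows")

    def expanded(self) -> "IsotopeScenario":
        """Resolve the near-collinear switch into an explicit twin source."""
        if not self.near_collinear:
            return self
        off = np.asarray(self.collinear_offset, float)[: self.mu.shape[1]]
        names = [*self.source_names, f"{self.source_names[0]}_twin"]
        mu = np.vstack([self.mu, self.mu[0] + off])
        sigma = np.vstack([self.sigma, self.sigma[0]])
        n = [*self.n_per_source, self.n_per_source[0]]
        p = np.concatenate([self.true_p, [self.true_p[0] / 2]])
        p[0] /= 2
        return IsotopeScenario(
            source_names=names, mu=mu, sigma=sigma, n_per_source=n,
            true_p=p, resid_sd=self.resid_sd, n_mixtures=self.n_mixtures,
            n_acid_fail=self.n_acid_fail,
            near_collinear=False, tracers=self.tracers,
        )


@dataclass
class IsotopeTruth:
    true_p: dict[str, float]
    resid_sd: np.ndarray
    seed: int | None


def generate_isotope_dataset(
    scenario: IsotopeScenario, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, IsotopeTruth]:
    """Draw source samples and mixture samples from the scenario.

    Returns
    -------
    (sources, mixtures, truth)
        ``sources``: one row per source sample (sample_id, category,
        sample_type = source name, tracer columns). ``mixtures``: one row
        per mixture sample. ``truth`` carries the true proportions.
    """
    sc = scenario.expanded()
    rng = np.random.default_rng(seed)
    J = sc.mu.shape[1]
    resid = np.broadcast_to(np.asarray(sc.resid_sd, float), (J,))

    rows = []
    for k, name in enumerate(sc.source_names):
        for i in range(sc.n_per_source[k]):
            vals = rng.normal(sc.mu[k], sc.sigma[k])
            row = {"sample_id": f"src_{name}_{i}", "category": "source",
                   "sample_type": name}
            row.update(dict(zip(sc.tracers, vals)))
            rows.append(row)
    sources = pd.DataFrame(rows)
    if sc.n_acid_fail:
        # incomplete acidification leaves inorganic carbon: d13C jumps well
        # above the -10 permil QC cutoff
        fail_idx = rng.choice(len(sources), size=sc.n_acid_fail, replace=False)
        sources.loc[fail_idx, "d13c"] = rng.uniform(-8.0, -2.0, sc.n_acid_fail)

    mix_mean = sc.true_p @ sc.mu
    mix_sd = np.sqrt((sc.true_p**2) @ (sc.sigma**2) + resid**2)
    mrows = []
    for i in range(sc.n_mixtures):
        vals = rng.normal(mix_mean, mix_sd)
        row = {"sample_id": f"mix_{i}", "category": "detritus",
               "sample_type": "mixture"}
        row.update(dict(zip(sc.tracers, vals)))
        mrows.append(row)
    mixtures = pd.DataFrame(mrows)

    truth = IsotopeTruth(
        true_p=dict(zip(sc.source_names, sc.true_p)),
        resid_sd=np.array(resid),
        seed=seed,
    )
    return sources, mixtures, truth


def source_grouping(sources: pd.DataFrame) -> dict[str, list[str]]:
    """Sample-id grouping by source name, ready for summarize_sources."""
    return {
        name: list(grp["sample_id"])
        for name, grp in sources.groupby("sample_type", sort=False)
    }


def default_isotope_scenario(**overrides) -> IsotopeScenario:
    """Four well-separated sources, true p = (0.6, 0.2, 0.15, 0.05).

    With four sources and two tracers the proportion vector is identified
    only up to a one-dimensional null direction of the mixing polytope;
    the layout here places the true proportions at the center of the
    feasible segment along that direction, so the model is informative
    about every source despite K > J + 1.
    """
    base = dict(
        source_names=("algae", "sponge", "cyanomat", "plankton"),
        mu=[[-25.0, 6.0], [-16.0, 2.4], [-13.0, 1.2], [-19.0, -2.0]],
        sigma=np.full((4, 2), 0.5),
        n_per_source=(5, 5, 5, 5),
        true_p=(0.6, 0.2, 0.15, 0.05),
        resid_sd=0.5,
        n_mixtures=10,
    )
    base.update(overrides)
    return IsotopeScenario(**base)


# --------------------------------------------------------------------------
# eDNA arm
# --------------------------------------------------------------------------

#: Default reef taxon pool: full six-rank lineages plus the rank depth to
#: which the generator makes each taxon's ESVs assignable.
_DEFAULT_TAXA = [
    # phylum, class, order, family, genus, species, intended_depth
    ("Arthropoda", "Hexanauplia", "Harpacticoida", "Miraciidae", "Macrosetella", "Macrosetella gracilis", "species"),
    ("Arthropoda", "Hexanauplia", "Cyclopoida", "Oithonidae", "Oithona", "Oithona nana", "species"),
    ("Porifera", "Demospongiae", "Verongiida", "Aplysinidae", "Aplysina", "Aplysina cauliformis", "species"),
    ("Porifera", "Demospongiae", "Chondrillida", "Halisarcidae", "Halisarca", "Halisarca caerulea", "family"),
    ("Cnidaria", "Octocorallia", "Alcyonacea", "Plexauridae", "Eunicea", "Eunicea flexuosa", "species"),
    ("Cnidaria", "Hexacorallia", "Scleractinia", "Merulinidae", "Orbicella", "Orbicella annularis", "genus"),
    ("Mollusca", "Gastropoda", "Caenogastropoda", "Cerithiidae", "Cerithium", "Cerithium litteratum", "species"),
    ("Annelida", "Polychaeta", "Phyllodocida", "Syllidae", "Syllis", "Syllis gracilis", "genus"),
    ("Nematoda", "Chromadorea", "Chromadorida", "Chromadoridae", "Chromadorina", "Chromadorina germanica", "genus"),
    ("Xenacoelomorpha", "Acoelomorpha", "Acoela", "Convolutidae", "Waminoa", "Waminoa litus", "family"),
    ("Platyhelminthes", "Rhabditophora", "Polycladida", "Leptoplanidae", "Leptoplana", "Leptoplana tremellaris", "order"),
    ("Bacillariophyta", "Bacillariophyceae", "Naviculales", "Naviculaceae", "Navicula", "Navicula ramosissima", "species"),
    ("Rhodophyta", "Florideophyceae", "Ceramiales", "Rhodomelaceae", "Neosiphonia", "Neosiphonia howei", "genus"),
    ("Cyanobacteria", "Cyanophyceae", "Oscillatoriales", "Microcoleaceae", "Moorea", "Moorea producens", "species"),
    ("Chlorophyta", "Ulvophyceae", "Bryopsidales", "Halimedaceae", "Halimeda", "Halimeda opuntia", "species"),
    ("Ochrophyta", "Phaeophyceae", "Dictyotales", "Dictyotaceae", "Lobophora", "Lobophora variegata", "species"),
]

_METAZOA = {
    "Arthropoda", "Porifera", "Cnidaria", "Mollusca", "Annelida",
    "Nematoda", "Xenacoelomorpha", "Platyhelminthes", "Chordata",
}

_CONTAMINANTS = [
    ("Chordata", "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens"),
    ("Actinobacteria", "Actinomycetia", "Propionibacteriales",
     "Propionibacteriaceae", "Cutibacterium", "Cutibacterium acnes"),
]

#: Identity band (coverage fixed at 100) realizing each intended depth.
#: Bands sit strictly inside the rank thresholds so boundary arithmetic
#: never decides an assignment.
_DEPTH_BANDS = {
    "species": (99.05, 99.95),
    "genus": (98.05, 98.95),
    "family": (95.05, 97.95),
    "order": (90.05, 94.95),
    "class": (90.05, 94.95),   # plus lineage truncated below class
    "phylum": (85.05, 89.95),
}


def default_taxa() -> pd.DataFrame:
    return pd.DataFrame(
        _DEFAULT_TAXA, columns=[*RANKS, "intended_depth"]
    )


@dataclass
class EdnaScenario:
    """Controls for the multi-marker eDNA community simulation."""

    taxa: pd.DataFrame = field(default_factory=default_taxa)
    #: group label -> number of samples
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"J18 EAM": 5, "M19 EAM": 6, "M19 tray": 2}
    )
    #: group label -> sample type (for frequency denominators)
    group_sample_type: Mapping[str, str] | None = None
    #: group label -> per-taxon occurrence probability vector
    occurrence: Mapping[str, Sequence[float]] | None = None
    markers: Sequence[str] = ("COI", "18S", "16S")
    dropout: float = 0.1
    esvs_per_taxon: int = 1
    contamination_rate: float = 0.1
    n_batches: int = 2
    decoy_hits: bool = True

    def __post_init__(self) -> None:
        if self.taxa.empty:
            raise ValueError("taxon pool must be non-empty")
        if not (0 <= self.dropout <= 1) or not (0 <= self.contamination_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("need at least one batch (each with a negative control)")
        if self.group_sample_type is None:
            self.group_sample_type = {
                g: g.split(" ", 1)[1] if " " in g else g
                for g in self.samples_per_group
            }
        if self.occurrence is None:
            T = len(self.taxa)
            rngless = {}
            for gi, g in enumerate(self.samples_per_group):
                # group-structured baseline: alternate high/low blocks so
                # groups differ in composition
                probs = np.where(
                    (np.arange(T) + gi) % 3 == 0, 0.9,
                    np.where((np.arange(T) + gi) % 3 == 1, 0.5, 0.2),
                )
                rngless[g] = probs
            self.occurrence = rngless
        for g, p in self.occurrence.items():
            p = np.asarray(p, float)
            if p.shape != (len(self.taxa),) or np.any((p < 0) | (p > 1)):
                raise ValueError(f"occurrence for {g!r} must be {len(self.taxa)} probabilities")

    def marker_affinity(self) -> pd.DataFrame:
        """Which marker can detect which taxon (1 = detectable)."""
        aff = pd.DataFrame(0, index=self.taxa.index, columns=list(self.markers))
        phyla = self.taxa["phylum"]
        if "COI" in aff.columns:
            aff.loc[phyla.isin(_METAZOA), "COI"] = 1
        if "18S" in aff.columns:
            aff.loc[phyla != "Cyanobacteria", "18S"] = 1
        if "16S" in aff.columns:
            aff.loc[phyla == "Cyanobacteria", "16S"] = 1
        return aff


@dataclass
class EdnaDataset:
    """Simulated multi-marker bundle plus its ground truth."""

    metadata: pd.DataFrame
    hit_tables: dict[str, pd.DataFrame]
    detections: dict[str, pd.DataFrame]
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata.loc[~self.metadata["is_negative"], "sample_id"])


def _hit_rows(esv_id, marker, lineage, depth, rng, decoy: bool) -> list[dict]:
    lo, hi = _DEPTH_BANDS[depth]
    identity = round(float(rng.uniform(lo, hi)), 2)
    names = dict(zip(RANKS, lineage))
    if depth in ("class", "phylum"):
        cut = RANKS.index(depth)
        for r in RANKS[cut + 1:]:
            names[r] = None
    rows = [{
        "esv_id": esv_id, "marker": marker, **names,
        "pct_identity": identity, "pct_coverage": 100.0,
        "evalue": float(rng.uniform(1e-30, 1e-10)),
    }]
    if decoy:
        decoy_names = dict(names)
        for r in RANKS[1:]:
            if decoy_names.get(r):
                decoy_names[r] = f"{decoy_names[r]}_decoy"
        rows.append({
            "esv_id": esv_id, "marker": marker, **decoy_names,
            "pct_identity": round(float(rng.uniform(70.0, 84.0)), 2),
            "pct_coverage": 100.0,
            "evalue": float(rng.uniform(1e-8, 1e-4)),
        })
    return rows


def generate_edna_dataset(scenario: EdnaScenario, seed: int | None = None) -> EdnaDataset:
    """Simulate metadata, hit tables and detection matrices with truth."""
    rng = np.random.default_rng(seed)
    taxa = scenario.taxa.reset_index(drop=True)
    T = len(taxa)
    aff = scenario.marker_affinity().reset_index(drop=True)

    # --- samples and batches -------------------------------------------------
    meta_rows = []
    for g, n in scenario.samples_per_group.items():
        stype = scenario.group_sample_type[g]
        for i in range(n):
            meta_rows.append({
                "sample_id": f"{g.replace(' ', '_')}_{i}",
                "group": g, "sample_type": stype,
                "season": g.split(" ", 1)[0],
                "is_negative": False,
            })
    for b in range(scenario.n_batches):
        meta_rows.append({
            "sample_id": f"NEG_b{b}", "group": "negative",
            "sample_type": "negative control", "season": "",
            "is_negative": True,
        })
    metadata = pd.DataFrame(meta_rows)
    real = metadata.loc[~metadata["is_negative"]].reset_index(drop=True)
    metadata["batch"] = ""
    batches = [f"b{i % scenario.n_batches}" for i in range(len(real))]
    metadata.loc[~metadata["is_negative"], "batch"] = batches
    metadata.loc[metadata["is_negative"], "batch"] = [
        f"b{b}" for b in range(scenario.n_batches)
    ]

    # --- true community ------------------------------------------------------
    presence = np.zeros((len(real), T), dtype=int)
    for i, row in real.iterrows():
        probs = np.asarray(scenario.occurrence[row["group"]], float)
        present = rng.random(T) < probs
        if not present.any():
            present[int(np.argmax(probs))] = True  # no empty communities
        presence[i] = present.astype(int)
    truth_presence = pd.DataFrame(presence, index=real["sample_id"], columns=taxa["species"])

    # --- ESVs and hit tables -------------------------------------------------
    esv_of_taxon: dict[str, list[tuple[int, str]]] = {m: [] for m in scenario.markers}
    hit_rows: dict[str, list[dict]] = {m: [] for m in scenario.markers}
    for ti in range(T):
        lineage = tuple(taxa.loc[ti, list(RANKS)])
        depth = taxa.loc[ti, "intended_depth"]
        for m in scenario.markers:
            if aff.loc[ti, m] == 0:
                continue
            for j in range(scenario.esvs_per_taxon):
                esv = f"{m}_t{ti:02d}_e{j}"
                esv_of_taxon[m].append((ti, esv))
                hit_rows[m].extend(
                    _hit_rows(esv, m, lineage, depth, rng, scenario.decoy_hits)
                )

    # contaminant ESVs (one per contaminant taxon, on the COI marker)
    contam_marker = scenario.markers[0]
    contam_esvs = []
    for ci, lineage in enumerate(_CONTAMINANTS):
        esv = f"{contam_marker}_contam{ci}"
        contam_esvs.append(esv)
        hit_rows[contam_marker].extend(
            _hit_rows(esv, contam_marker, lineage, "species", rng, False)
        )
    hit_tables = {
        m: pd.DataFrame(rows, columns=["esv_id", "marker", *RANKS,
                                       "pct_identity", "pct_coverage", "evalue"])
        for m, rows in hit_rows.items()
    }

    # --- detections -----------------------------------------------------------
    all_ids = list(metadata["sample_id"])
    batch_of = dict(zip(metadata["sample_id"], metadata["batch"]))
    detections = {}
    for m in scenario.markers:
        cols = [esv for _, esv in esv_of_taxon[m]]
        if m == contam_marker:
            cols = cols + contam_esvs
        det = pd.DataFrame(0, index=all_ids, columns=cols, dtype=int)
        for i, row in real.iterrows():
            sid = row["sample_id"]
            for ti, esv in esv_of_taxon[m]:
                if presence[i, ti] and rng.random() >= scenario.dropout:
                    det.loc[sid, esv] = 1
        detections[m] = det

    # contaminants: always in each batch's negative, sporadically in samples
    negatives = list(metadata.loc[metadata["is_negative"], "sample_id"])
    det_c = detections[contam_marker]
    for esv in contam_esvs:
        for neg in negatives:
            det_c.loc[neg, esv] = 1
            batch = batch_of[neg]
            for sid in real["sample_id"]:
                if batch_of[sid] == batch and rng.random() < scenario.contamination_rate:
                    det_c.loc[sid, esv] = 1

    truth = {
        "taxa": taxa,
        "presence": truth_presence,
        "intended_depth": dict(zip(taxa["species"], taxa["intended_depth"])),
        "contaminant_esvs": contam_esvs,
        "seed": seed,
    }
    return EdnaDataset(metadata=metadata, hit_tables=hit_tables,
                       detections=detections, truth=truth)


def true_rank_presence(dataset: EdnaDataset, rank: str) -> pd.DataFrame:
    """Collapse the true species-level community to a coarser rank."""
    taxa = dataset.truth["taxa"]
    presence = dataset.truth["presence"]
    names = sorted(taxa[rank].dropna().unique())
    out = pd.DataFrame(0, index=presence.index, columns=names, dtype=int)
    for _, row in taxa.iterrows():
        if pd.isna(row[rank]):
            continue
        hit = presence[row["species"]] > 0
        out.loc[hit, row[rank]] = 1
    return out


# --------------------------------------------------------------------------
# study-shaped default fixtures
# --------------------------------------------------------------------------


def reef_study_scenarios() -> dict:
    """Scenario bundle shaped like a two-season Caribbean forereef campaign.

    Replicate counts follow the field design (e.g. 5 sequenced EAM detritus
    samples in July 2018, 6 in March 2019, 2 tray samples; a single 2018
    spongivore-feces isotope sample) and the isotope layout places sponge
    tissues higher in d15N than algae and mats, with sediment-trap
    particulates depleted in both tracers.
    """
    names = (
        "algae", "BCM", "herbivore feces", "spongivore feces",
        "Aplysina cauliformis", "Niphates digitalis", "Xestospongia muta",
        "Chondrilla sp", "Halisarca caerulea", "Scopalina ruetzleri",
        "sediment trap",
    )
    mu = np.array([
        [-18.0, 0.5],    # algae
        [-21.1, 0.8],    # benthic cyanobacterial mat
        [-17.9, 0.65],   # herbivore feces (overlaps algae, as observed)
        [-15.5, 3.5],    # spongivore feces (tracks sponges)
        [-18.5, 3.0],    # Aplysina cauliformis
        [-16.5, 4.0],    # Niphates digitalis
        [-17.0, 3.5],    # Xestospongia muta
        [-18.0, 3.2],    # Chondrilla sp
        [-17.9, 4.5],    # Halisarca caerulea
        [-14.5, 5.5],    # Scopalina ruetzleri
        [-20.0, -1.1],   # sediment trap
    ])
    sigma = np.array([
        [1.0, 0.6], [0.1, 0.4], [0.9, 0.7], [0.5, 0.5],
        [0.6, 0.5], [0.7, 0.5], [0.8, 0.5], [0.6, 0.5],
        [1.4, 0.6], [0.9, 0.6], [0.8, 1.3],
    ])
    true_p = np.array([0.40, 0.06, 0.12, 0.02, 0.04, 0.04, 0.04,
                       0.04, 0.04, 0.04, 0.16])
    iso_2018 = IsotopeScenario(
        source_names=names, mu=mu, sigma=sigma,
        n_per_source=(10, 3, 5, 1, 10, 8, 10, 2, 3, 3, 5),
        true_p=true_p, resid_sd=0.4, n_mixtures=5,
    )
    iso_2019 = IsotopeScenario(
        source_names=names, mu=mu + np.array([0.3, -0.2]), sigma=sigma,
        n_per_source=(14, 5, 5, 3, 10, 10, 10, 3, 4, 5, 14),
        true_p=true_p, resid_sd=0.8, n_mixtures=11,
        n_acid_fail=8,   # the spring campaign lost 8 samples to incomplete acidification
    )

    taxa = default_taxa()
    T = len(taxa)
    phylum = taxa["phylum"]
    base = np.full(T, 0.35)
    base[phylum.isin(["Bacillariophyta", "Rhodophyta", "Cyanobacteria"])] = 0.95
    base[phylum == "Arthropoda"] = 0.8
    base[phylum == "Porifera"] = 0.5
    base[phylum.isin(["Chlorophyta", "Ochrophyta"])] = 0.7
    occurrence = {
        "J18 EAM": np.clip(base + 0.05, 0, 1),
        "M19 EAM": np.clip(base - 0.35, 0.05, 1),
        "M19 tray": np.clip(base - 0.15, 0.05, 1),
        "J18 sed trap": np.clip(np.where(phylum == "Porifera", 0.85, base), 0, 1),
        "M19 sed trap": np.clip(np.where(phylum == "Porifera", 0.85, base) - 0.2, 0.05, 1),
        "J18 hvore feces": np.clip(base - 0.25, 0.05, 1),
        "M19 hvore feces": np.clip(base - 0.25, 0.05, 1),
        "J18 svore feces": np.clip(np.where(phylum.isin(["Cnidaria", "Porifera", "Chordata"]), 0.7, 0.2), 0, 1),
        "M19 svore feces": np.clip(np.where(phylum.isin(["Cnidaria", "Porifera", "Chordata"]), 0.7, 0.2), 0, 1),
    }
    samples = {
        "J18 EAM": 5, "M19 EAM": 6, "M19 tray": 2,
        "J18 sed trap": 5, "M19 sed trap": 7,
        "J18 hvore feces": 5, "M19 hvore feces": 7,
        "J18 svore feces": 1, "M19 svore feces": 4,
    }
    types = {
        "J18 EAM": "EAM", "M19 EAM": "EAM", "M19 tray": "tray",
        "J18 sed trap": "sediment trap", "M19 sed trap": "sediment trap",
        "J18 hvore feces": "herbivore feces", "M19 hvore feces": "herbivore feces",
        "J18 svore feces": "spongivore feces", "M19 svore feces": "spongivore feces",
    }
    edna = EdnaScenario(
        taxa=taxa, samples_per_group=samples, group_sample_type=types,
        occurrence=occurrence, dropout=0.1, contamination_rate=0.1,
        n_batches=2,
    )
    return {"isotope_2018": iso_2018, "isotope_2019": iso_2019, "edna": edna}
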