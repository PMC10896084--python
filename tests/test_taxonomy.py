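import itertools

import numpy as np
import pandas as pd
import pytest

from detritrace import taxonomy as tx
from tests.conftest import make_hits

L_SPONGE = ("Porifera", "Demospongiae", "Chondrillida", "Halisarcidae", "Halisarca", "Halisarca caerulea")
L_COPEPOD = ("Arthropoda", "Hexanauplia", "Harpacticoida", "Miraciidae", "Macrosetella", "Macrosetella gracilis")


class TestSimilarityScore:
    @pytest.mark.parametrize(
        "identity,coverage,expected",
        [(100, 100, 100.0), (96, 100, 96.0), (99, 97, 96.03), (0, 50, 0.0)],
    )
    def test_product_rule(self, identity, coverage, expected):
        assert tx.similarity_score(identity, coverage) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.similarity_score(101, 50)
        with pytest.raises(ValueError):
            tx.similarity_score(50, -1)


class TestEvalueFilter:
    def test_boundary_inclusive(self):
        hits = make_hits([
            ("e1", "COI", L_SPONGE, 99, 100, 0.001),
            ("e1", "COI", L_SPONGE, 99, 100, 0.01),
        ])
        kept = tx.filter_hits(hits)
        assert list(kept["evalue"]) == [0.001]

    def test_all_hits_removed_leaves_empty_table(self):
        assert tx.filter_hits(make_hits([("e", "COI", L_SPONGE, 99, 100, 1.0)])).empty


class TestAssignRanks:
    def test_family_assigned_genus_below_threshold(self):
        # a 96-scoring hit clears phylum..family but not the 98 genus bar
        hits = make_hits([("e1", "COI", L_SPONGE, 96, 100, 1e-20)])
        a = tx.assign_ranks(hits)
        assert a.assigned["family"] == "Halisarcidae"
        assert a.assigned["genus"] is None
        assert a.assigned["species"] is None
        assert a.best_score["genus"] == pytest.approx(96.0)

    def test_tied_distinct_genera_leave_rank_undefined(self):
        g1 = L_SPONGE
        g2 = L_SPONGE[:4] + ("Chondrilla", "Chondrilla nucula")
        hits = make_hits([
            ("e1", "COI", g1, 99, 100, 1e-20),
            ("e1", "COI", g2, 99, 100, 1e-20),
        ])
        a = tx.assign_ranks(hits)
        assert a.assigned["family"] == "Halisarcidae"
        assert a.assigned["genus"] is None
        assert a.assigned["species"] is None

    def test_score_below_phylum_assigns_nothing(self):
        hits = make_hits([("e1", "COI", L_SPONGE, 84, 100, 1e-20)])
        a = tx.assign_ranks(hits)
        assert all(v is None for v in a.assigned.values())

    def test_blank_species_leaves_species_undefined(self):
        hits = make_hits([("e1", "COI", L_SPONGE[:5], 99.5, 100, 1e-20)])
        a = tx.assign_ranks(hits)
        assert a.assigned["genus"] == "Halisarca"
        assert a.assigned["species"] is None

    def test_assignments_are_lineage_prefixes(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            hits = _random_hits(rng)
            a = tx.assign_ranks(hits)
            seen_gap = False
            for r in tx.RANKS:
                if a.assigned[r] is None:
                    seen_gap = True
                else:
                    assert not seen_gap  # no assignment below an undefined rank

    def test_raising_threshold_never_adds_assignments(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            hits = _random_hits(rng)
            base = tx.assign_ranks(hits)
            higher = dict(tx.DEFAULT_RANK_THRESHOLDS)
            higher["family"] = 99.0
            higher["genus"] = 99.0
            stricter = tx.assign_ranks(hits, higher)
            for r in tx.RANKS:
                if stricter.assigned[r] is not None:
                    assert stricter.assigned[r] == base.assigned[r]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            hits = _random_hits(rng)
            a = tx.assign_ranks(hits)
            assert a.assigned == _oracle_assign(hits)


def _random_hits(rng, max_hits=8):
    phyla = ["Porifera", "Arthropoda"]
    rows = []
    n = rng.integers(1, max_hits + 1)
    for _ in range(n):
        ph = rng.choice(phyla)
        lineage = [ph] + [f"{ph[:3]}_{r}{rng.integers(0, 2)}" for r in tx.RANKS[1:]]
        depth = rng.integers(1, 7)
        lineage = lineage[:depth]
        ident = float(rng.choice([80, 84, 85, 90, 94, 95, 96, 98, 99, 100]))
        cov = float(rng.choice([90, 95, 100]))
        rows.append(("esv", "COI", tuple(lineage), ident, cov, 1e-10))
    return make_hits(rows)


def _oracle_assign(hits):
    """Exhaustive re-derivation of the top-down assignment rule."""
    from decimal import Decimal

    def score(row):
        return Decimal(str(row["pct_identity"])) * Decimal(str(row["pct_coverage"])) / 100

    assigned = {r: None for r in tx.RANKS}
    parents = {}
    for r in tx.RANKS:
        candidates = {}
        for _, row in hits.iterrows():
            name = row[r]
            if pd.isna(name) or name == "":
                continue
            if any(pd.isna(row[pr]) or row[pr] != pv for pr, pv in parents.items()):
                continue
            s = score(row)
            candidates.setdefault(name, []).append(s)
        if not candidates:
            break
        best = max(max(v) for v in candidates.values())
        top = [n for n, v in candidates.items() if max(v) == best]
        if len(top) > 1 or best < Decimal(str(tx.DEFAULT_RANK_THRESHOLDS[r])):
            break
        assigned[r] = top[0]
        parents[r] = top[0]
    return assigned


class TestDecontamination:
    def _detections(self):
        idx = ["s1", "s2", "s3", "s4", "neg1", "neg2"]
        det = pd.DataFrame(0, index=idx, columns=["e1", "e2", "e3"])
        det.loc[["s1", "s2", "s3"], "e1"] = 1      # batch-1 contaminant
        det.loc["neg1", "e1"] = 1
        det.loc["s4", "e2"] = 1                    # batch-2 only, clean
        det.loc["neg1", "e3"] = 1                  # negative-only ESV
        det.loc["s4", "e1"] = 1                    # batch-2 detection of e1
        return det

    def _batches(self):
        return {"s1": "b1", "s2": "b1", "s3": "b1", "s4": "b2",
                "neg1": "b1", "neg2": "b2"}

    def test_removed_from_same_batch_only(self):
        cleaned, log = tx.remove_negative_control_esvs(
            self._detections(), ["neg1", "neg2"], self._batches()
        )
        assert (cleaned.loc[["s1", "s2", "s3"], "e1"] == 0).all()
        assert cleaned.loc["s4", "e1"] == 1   # other batch retained
        assert cleaned.loc["s4", "e2"] == 1

    def test_negatives_dropped_and_counts_partition(self):
        det = self._detections()
        cleaned, log = tx.remove_negative_control_esvs(det, ["neg1", "neg2"], self._batches())
        assert not {"neg1", "neg2"} & set(cleaned.index)
        removed = int(log["samples_affected"].sum())
        before = int(det.drop(index=["neg1", "neg2"]).to_numpy().sum())
        after = int(cleaned.to_numpy().sum())
        assert before == after + removed

    def test_sample_without_batch_rejected(self):
        det = self._detections()
        batches = self._batches()
        del batches["s2"]
        with pytest.raises(KeyError, match="s2"):
            tx.remove_negative_control_esvs(det, ["neg1", "neg2"], batches)


class TestBlocklistAndVerification:
    def _table(self):
        return pd.DataFrame([
            {"sample_id": "s1", **dict(zip(tx.RANKS, L_SPONGE))},
            {"sample_id": "s1", **dict(zip(tx.RANKS, ("Chordata", "Mammalia", "Primates",
                                                      "Hominidae", "Homo", "Homo sapiens")))},
            {"sample_id": "s2", **dict(zip(tx.RANKS, L_COPEPOD))},
        ])

    def test_human_reads_removed(self):
        out = tx.apply_taxon_blocklist(self._table())
        assert "Homo sapiens" not in set(out["species"])
        assert len(out) == 2

    def test_empty_blocklist_is_identity(self):
        t = self._table()
        assert tx.apply_taxon_blocklist(t, []).equals(t)

    def test_genus_entry_removes_member_species(self):
        out = tx.apply_taxon_blocklist(self._table(), ["Halisarca"])
        assert "Halisarca caerulea" not in set(out["species"])

    def test_verify_names_flags_and_strict_drop(self):
        t = self._table()
        valid = set(itertools.chain(L_SPONGE, L_COPEPOD))
        out = tx.verify_names(t, valid)
        assert out["verified"].tolist() == [True, False, True]
        strict = tx.verify_names(t, valid, strict=True)
        assert len(strict) == 2

    def test_empty_list_nonstrict_keeps_all(self):
        out = tx.verify_names(self._table(), [])
        assert (~out["verified"]).all()
        assert len(out) == 3


class TestConsolidation:
    def test_union_with_provenance(self):
        a_coi = tx.assign_ranks(make_hits([("c1", "COI", L_SPONGE, 99.5, 100, 1e-20)]))
        a_18s = tx.assign_ranks(make_hits([("r1", "18S", L_SPONGE, 99.5, 100, 1e-20)]))
        a_18s2 = tx.assign_ranks(make_hits([("r2", "18S", L_COPEPOD, 99.5, 100, 1e-20)]))
        det_coi = pd.DataFrame({"c1": [1, 0]}, index=["s1", "s2"])
        det_18s = pd.DataFrame({"r1": [1, 0], "r2": [0, 1]}, index=["s1", "s2"])
        table = tx.consolidate_markers(
            {"COI": [a_coi], "18S": [a_18s, a_18s2]},
            {"COI": det_coi, "18S": det_18s},
        )
        # same lineage via two markers collapses with both markers recorded
        sponge_rows = table.loc[table["species"] == "Halisarca caerulea"]
        assert len(sponge_rows) == 1
        assert sponge_rows.iloc[0]["markers"] == "18S;COI"
        # single-marker taxon present via union
        assert (table["species"] == "Macrosetella gracilis").sum() == 1

    def test_conflicting_species_kept_distinct(self):
        l2 = L_SPONGE[:5] + ("Halisarca dujardinii",)
        a1 = tx.assign_ranks(make_hits([("c1", "COI", L_SPONGE, 99.5, 100, 1e-20)]))
        a2 = tx.assign_ranks(make_hits([("r1", "18S", l2, 99.5, 100, 1e-20)]))
        det = pd.DataFrame({"c1": [1]}, index=["s1"])
        det2 = pd.DataFrame({"r1": [1]}, index=["s1"])
        table = tx.consolidate_markers({"COI": [a1], "18S": [a2]}, {"COI": det, "18S": det2})
        assert set(table["species"]) == {"Halisarca caerulea", "Halisarca dujardinii"}
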