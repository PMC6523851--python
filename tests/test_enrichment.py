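"""EASE scoring against exact enumeration, enrichment and deconvolution."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from komix.enrichment import (
    EnrichmentRow,
    deconvolute_contributors,
    ease_score,
    enrich,
    joint_union,
    resolve_cross_omics_conflicts,
    stars,
    table2_frame,
)
from komix.io_formats import PathwayDB, ValidationError
from komix.ko_inference import ContributionTable
from komix.ko_mapping import KoSet


def ease_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact-integer enumeration of the penalized hypergeometric upper tail."""
    if k <= 1:
        return 1.0
    n1, K1, N1 = n - 1, K - 1, N - 1
    total = math.comb(N1, n1)
    tail = sum(
        math.comb(K1, i) * math.comb(N1 - K1, n1 - i)
        for i in range(k - 1, min(n1, K1) + 1)
    )
    return tail / total


class TestEaseScore:
    @pytest.mark.parametrize("k", [0, 1])
    def test_single_hit_penalty_gives_one(self, k):
        assert ease_score(k, 10, 20, 200) == 1.0
        assert ease_score(k, max(k, 1), max(k, 1), 5) == 1.0

    def test_complete_overlap_matches_enumeration(self):
        for m in (2, 5, 9):
            assert ease_score(m, m, m, m) == pytest.approx(
                ease_oracle(m, m, m, m), abs=1e-12)

    def test_frozen_reference_value(self):
        # enumeration oracle value for the (2, 7, 17, 174) penalized table
        p = ease_score(3, 10, 20, 200)
        assert p == pytest.approx(0.20751658473264, abs=1e-12)
        assert p >= hypergeom.sf(2, 200, 20, 10)  # more conservative

    def test_penalized_never_below_fisher(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(4, 500))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert ease_score(k, n, K, N) >= \
                ease_score(k, n, K, N, penalized=False) - 1e-12

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(2, 400))
        n = data.draw(st.integers(1, N))
        K = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        assert ease_score(k, n, K, N) == pytest.approx(
            ease_oracle(k, n, K, N), abs=1e-12)

    def test_monotone_in_hits(self):
        n, K, N = 15, 30, 300
        ps = [ease_score(k, n, K, N) for k in range(min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValidationError):
            ease_score(5, 4, 10, 100)   # k > n
        with pytest.raises(ValidationError):
            ease_score(2, 5, 200, 100)  # K > N


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"),
        (0.05, "*"), (0.06, ""),
    ])
    def test_thresholds(self, p, expected):
        assert stars(p) == expected


def _koset(comparison, direction, kos, source="microbiome"):
    return KoSet(comparison, direction, set(kos),
                 {k: {source} for k in kos})


class TestEnrich:
    def test_disjoint_pathway_scores_one(self):
        universe = {f"K{i}" for i in range(100)}
        listed = _koset("A-B", "UP", [f"K{i}" for i in range(10)])
        db = PathwayDB(members={"p1": {f"K{i}" for i in range(90, 99)}})
        rows = enrich(listed, db, universe)
        assert rows[0].p_ease == 1.0 and rows[0].k == 0

    def test_planted_pathway_ranks_first(self):
        universe = {f"K{i}" for i in range(400)}
        cassette = [f"K{i}" for i in range(12)]
        listed = _koset("A-B", "UP", cassette + [f"K{i}" for i in range(100, 108)])
        rng = np.random.default_rng(1)
        members = {"planted": set(cassette)}
        for j in range(10):
            members[f"bg{j}"] = {
                f"K{i}" for i in rng.integers(12, 400, size=15)}
        rows = enrich(listed, PathwayDB(members=members), universe)
        assert rows[0].pathway_id == "planted"
        assert rows[0].p_ease == pytest.approx(
            ease_oracle(12, 20, 12, 400), abs=1e-12)

    def test_small_pathways_skipped_and_sorted(self):
        universe = {f"K{i}" for i in range(50)}
        db = PathwayDB(members={"tiny": {"K1", "K2"},
                                "ok": {f"K{i}" for i in range(10)}})
        rows = enrich(_koset("A-B", "ALL", ["K1"]), db, universe)
        assert [r.pathway_id for r in rows] == ["ok"]

    def test_empty_universe_is_an_error(self):
        db = PathwayDB(members={"p": {"K1", "K2", "K3"}})
        with pytest.raises(ValidationError):
            enrich(_koset("A-B", "UP", ["K1"]), db, set())


class TestJointUnion:
    def test_merges_sets_and_provenance(self):
        gi = _koset("A-B", "UP", ["K1", "K2"])
        pbmc = KoSet("A-B", "UP", {"K2", "K3"},
                     {"K2": {"GeneX"}, "K3": {"GeneY"}})
        joint = joint_union(pbmc, gi)
        assert joint.kos == {"K1", "K2", "K3"}
        assert joint.provenance["K2"] == {"GeneX", "microbiome"}

    def test_empty_side_is_identity(self):
        gi = _koset("A-B", "DOWN", ["K1"])
        empty = KoSet("A-B", "DOWN", set(), {})
        assert joint_union(empty, gi).kos == gi.kos

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValidationError):
            joint_union(_koset("A-B", "UP", ["K1"]),
                        _koset("A-C", "UP", ["K1"]))

    def test_cross_omics_direction_clash_goes_to_all_only(self):
        h_up = KoSet("A-B", "UP", {"K1"}, {"K1": {"G1"}})
        h_down = KoSet("A-B", "DOWN", set(), {})
        h_all = KoSet("A-B", "ALL", {"K1"}, {"K1": {"G1"}})
        m_up = KoSet("A-B", "UP", set(), {})
        m_down = _koset("A-B", "DOWN", ["K1"])
        m_all = _koset("A-B", "ALL", ["K1"])
        up, down, all_ = resolve_cross_omics_conflicts(
            h_up, h_down, h_all, m_up, m_down, m_all)
        assert up.kos == set() and down.kos == set()
        assert all_.kos == {"K1"} and "K1" in all_.conflicts


class TestDeconvolution:
    def _row(self, hit_kos):
        return EnrichmentRow("p1", "Sphingolipid metabolism", "MS-MTXMS",
                             "ALL", len(hit_kos), 12, 20, 400, 1e-6, "***",
                             hit_kos=set(hit_kos))

    def test_cassette_taxa_recovered_exactly(self):
        records = pd.DataFrame(
            {
                "otu_id": ["O1", "O1", "O2", "O2"],
                "ko_id": ["K1", "K2", "K1", "K2"],
                "sample_id": ["s1"] * 4,
                "contribution": [6.0, 2.0, 1.0, 1.0],
            }
        )
        contrib = ContributionTable(records=records)
        tax = pd.Series(
            ["k__B;f__X;g__Akkermansia;s__", "k__B;f__X;g__Prevotella;s__"],
            index=["O1", "O2"])
        prov = {"K1": {"microbiome"}, "K2": {"microbiome", "B4galt6"}}
        row = deconvolute_contributors(
            self._row(["K1", "K2"]), contrib, prov,
            gene_directions={"B4galt6": "up"}, otu_taxonomy=tax,
            genus_directions={"Akkermansia": "up", "Prevotella": "down"})
        taxa = [t for t, _, _ in row.contributing_taxa]
        assert taxa == ["Akkermansia", "Prevotella"]  # ordered by share
        shares = [s for _, _, s in row.contributing_taxa]
        assert sum(shares) == pytest.approx(1.0, abs=1e-9)
        assert row.contributing_genes == [("B4galt6", "up")]

    def test_missing_contribution_records_rejected(self):
        contrib = ContributionTable(records=pd.DataFrame(
            {"otu_id": ["O1"], "ko_id": ["K9"], "sample_id": ["s1"],
             "contribution": [1.0]}))
        with pytest.raises(ValidationError):
            deconvolute_contributors(
                self._row(["K1"]), contrib, {"K1": {"microbiome"}},
                otu_taxonomy=pd.Series(["k__B;g__X;s__"], index=["O1"]))

    def test_report_schema(self):
        row = self._row(["K1"])
        row.contributing_genes = [("B4galt6", "up"), ("Ppap2c", "up"),
                                  ("Sptlc1", "up")]
        row.contributing_taxa = [("Akkermansia", "up", 0.5),
                                 ("Prevotella", "down", 0.3),
                                 ("Lactobacillus", "up", 0.2)]
        frame = table2_frame([row])
        assert list(frame.columns[:4]) == [
            "pathway", "genes", "microbes", "comparison_direction"]
        rec = frame.iloc[0]
        assert rec.pathway == "Sphingolipid metabolism"
        assert rec.genes == "B4galt6, Ppap2c, Sptlc1"
        assert rec.microbes == "Akkermansia, Prevotella, Lactobacillus"
        assert rec.comparison_direction == "MS-MTXMS_ALL"
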