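"""Gene retention/loss procedure: ordering, absent regions, translated
search and classification."""

import numpy as np
import pytest

from medsweep.io import GeneRecord
from medsweep.lossgain import (
    classify_retention_loss,
    define_absent_regions,
    order_pairs_and_mark_na,
    summarize_calls,
    translated_local_alignment,
)
from medsweep.simulate import _random_cds, sim_gene_order_pair


def g(gid, chrom, start, end):
    return GeneRecord(gid, chrom, start, end, "+")


class TestOrderAndMark:
    def test_order_preserved_and_na_marked(self):
        genes = [g("t1", "c1", 100, 200), g("t3", "c1", 500, 600),
                 g("t2", "c1", 300, 400), g("t4", "c1", 700, 800)]
        hits = {"t1": "r1", "t2": "r2", "t3": None, "t4": "r3"}
        ordered = order_pairs_and_mark_na(hits, genes)
        assert [x[0].gene_id for x in ordered] == ["t1", "t2", "t3", "t4"]
        assert [x[1] for x in ordered] == ["r1", "r2", None, "r3"]

    def test_empty_table(self):
        assert order_pairs_and_mark_na({}, []) == []

    def test_duplicate_ids_rejected(self):
        genes = [g("t1", "c1", 1, 10), g("t1", "c1", 20, 30)]
        with pytest.raises(ValueError):
            order_pairs_and_mark_na({"t1": "r1"}, genes)


class TestAbsentRegions:
    def test_interval_between_flanking_partners(self):
        ordered = [
            (g("t1", "c1", 1, 100), "r2"),
            (g("t2", "c1", 200, 300), None),
            (g("t3", "c1", 400, 500), "r3"),
        ]
        refs = {"r2": g("r2", "rc1", 10_000, 12_000), "r3": g("r3", "rc1", 30_000, 33_000)}
        regions = define_absent_regions(ordered, refs, {"rc1": 50_000})
        (reg,) = regions
        assert (reg.reference_chrom, reg.start, reg.end) == ("rc1", 12_001, 29_999)
        # never overlaps the flanking partners' spans
        assert reg.start > 12_000 and reg.end < 30_000

    def test_split_flanks_undefined(self):
        ordered = [
            (g("t1", "c1", 1, 100), "r1"),
            (g("t2", "c1", 200, 300), None),
            (g("t3", "c1", 400, 500), "r9"),
        ]
        refs = {"r1": g("r1", "rc1", 100, 200), "r9": g("r9", "rc4", 100, 200)}
        (reg,) = define_absent_regions(ordered, refs, {"rc1": 1000, "rc4": 1000})
        assert not reg.defined and reg.flank_status == "both"
        assert "split flanks" in reg.reason

    def test_chromosome_end_rule(self):
        ordered = [
            (g("t1", "c1", 1, 100), None),
            (g("t2", "c1", 200, 300), "r1"),
        ]
        refs = {"r1": g("r1", "rcX", 50_000, 52_000)}
        (reg,) = define_absent_regions(ordered, refs, {"rcX": 90_000})
        assert (reg.flank_status, reg.start, reg.end) == ("right_only", 1, 49_999)

    def test_all_na_gives_flankless_regions(self):
        ordered = [(g("t1", "c1", 1, 9), None), (g("t2", "c1", 20, 29), None)]
        regions = define_absent_regions(ordered, {}, {})
        assert all(r.flank_status == "none" and not r.defined for r in regions)

    def test_consecutive_na_share_nearest_paired_flanks(self):
        ordered = [
            (g("t1", "c1", 1, 10), "r1"),
            (g("t2", "c1", 20, 30), None),
            (g("t3", "c1", 40, 50), None),
            (g("t4", "c1", 60, 70), "r4"),
        ]
        refs = {"r1": g("r1", "rc1", 100, 200), "r4": g("r4", "rc1", 900, 1000)}
        regions = define_absent_regions(ordered, refs, {"rc1": 2000})
        assert len(regions) == 2
        assert all((r.start, r.end) == (201, 899) for r in regions)


class TestTranslatedAlignment:
    def test_exact_embedding_found_at_full_identity(self):
        rng = np.random.default_rng(4)
        cds = _random_cds(rng, 60)
        from Bio.Seq import Seq

        query = str(Seq(cds).translate()).rstrip("*")
        flank = "".join(np.random.default_rng(5).choice(list("ACGT"), 200))
        region = flank + cds + flank
        hit = translated_local_alignment(query, region)
        assert hit.identity_pct == 100.0 and hit.coverage_pct == 100.0

    def test_reverse_strand_embedding_found(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(6)
        cds = _random_cds(rng, 50)
        query = str(Seq(cds).translate()).rstrip("*")
        rc = str(Seq(cds).reverse_complement())
        region = "ACGT" * 30 + rc + "TTGCA" * 10
        hit = translated_local_alignment(query, region)
        assert hit.frame < 0 and hit.identity_pct == 100.0

    def test_random_region_rarely_clears_thresholds(self):
        """Empirical null: a 100 aa query vs random DNA stays below the
        50% identity + 50% coverage presence rule in >= 99/100 seeds."""
        from Bio.Seq import Seq

        rng = np.random.default_rng(7)
        cds = _random_cds(rng, 101)
        query = str(Seq(cds).translate()).rstrip("*")
        false_positives = 0
        for seed in range(100):
            region = "".join(np.random.default_rng(1000 + seed).choice(list("ACGT"), 1200))
            hit = translated_local_alignment(query, region)
            if hit and hit.identity_pct >= 50 and hit.coverage_pct >= 50:
                false_positives += 1
        assert false_positives <= 1

    def test_internal_stop_reduces_coverage(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(8)
        cds = _random_cds(rng, 80)
        query = str(Seq(cds).translate()).rstrip("*")
        broken = cds[:120] + "TAA" + cds[123:]  # plant a stop mid-frame
        hit = translated_local_alignment(query, broken)
        assert hit.coverage_pct < 100.0

    def test_all_n_region_unresolved(self):
        assert translated_local_alignment("M" + "A" * 20, "N" * 300) is None


@pytest.fixture(scope="module")
def sim():
    dels = [f"t{i:04d}" for i in range(20, 40)]
    unann = [f"t{i:04d}" for i in range(60, 65)]
    return sim_gene_order_pair(
        150, n_chroms=2, deletions=dels, unannotated_but_present=unann, seed=12
    ), dels, unann


class TestClassification:
    def test_planted_truth_recovered_exactly(self, sim):
        data, dels, unann = sim
        ordered = order_pairs_and_mark_na(data["best_hits"], data["target_genes"])
        ref_coords = {g.gene_id: g for g in data["ref_genes"]}
        regions = define_absent_regions(ordered, ref_coords, data["ref_chrom_lengths"])
        calls = classify_retention_loss(
            regions, data["target_proteins"], data["ref_genome"]
        )
        by_status = {}
        for c in calls:
            by_status.setdefault(c.status, set()).add(c.target_gene)
        assert by_status.get("lost_in_reference") == set(dels)
        assert by_status.get("present_unannotated") == set(unann)
        assert "unresolved" not in by_status
        assert summarize_calls(calls) == {
            "lost_in_reference": 20, "present_unannotated": 5, "unresolved": 0,
        }

    def test_zero_thresholds_call_everything_present(self, sim):
        data, dels, unann = sim
        ordered = order_pairs_and_mark_na(data["best_hits"], data["target_genes"])
        ref_coords = {g.gene_id: g for g in data["ref_genes"]}
        regions = define_absent_regions(ordered, ref_coords, data["ref_chrom_lengths"])
        calls = classify_retention_loss(
            regions, data["target_proteins"], data["ref_genome"],
            min_identity=0.0, min_coverage=0.0,
        )
        assert all(c.status == "present_unannotated" for c in calls)

    def test_no_na_genes_empty_calls(self):
        sim = sim_gene_order_pair(30, seed=3)
        ordered = order_pairs_and_mark_na(sim["best_hits"], sim["target_genes"])
        regions = define_absent_regions(
            ordered, {g.gene_id: g for g in sim["ref_genes"]}, sim["ref_chrom_lengths"]
        )
        assert regions == []
        assert classify_retention_loss(regions, {}, {}) == []
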