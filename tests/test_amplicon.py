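"""The OTU profiling pipeline, stage by stage and end to end."""

import math

import numpy as np
import pytest

from thiomarker.amplicon import (
    OtuCluster,
    Unique,
    anchor_on_primer,
    assign_taxonomy,
    cluster_greedy,
    dereplicate,
    expected_errors,
    map_reads,
    profile,
    quality_filter,
    screen_chimeras,
)
from thiomarker.markers import TILS_F
from thiomarker.pairwise import sequence_identity
from thiomarker.seqio import SequenceRecord

from conftest import mutate, random_seq


def read(rid, seq, q=40):
    return SequenceRecord(rid, seq, quality=[q] * len(seq))


class TestQualityFilter:
    def test_expected_error_arithmetic(self):
        # 300 bases at Q40 -> EE = 300 * 1e-4 = 0.03
        assert expected_errors([40] * 300) == pytest.approx(0.03)
        # 300 bases at Q10 -> EE = 30
        assert expected_errors([10] * 300) == pytest.approx(30.0)

    def test_keeps_good_drops_bad(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 300)
        kept, stats = quality_filter([read("good", seq, 40),
                                      read("bad", seq, 10)], 1.0)
        assert [r.id for r in kept] == ["good"]
        assert stats == {"kept": 1, "dropped_quality": 1, "dropped_length": 0}

    def test_infinite_budget_passes_all(self):
        rng = np.random.default_rng(1)
        reads = [read(f"r{i}", random_seq(rng, 100), 2) for i in range(5)]
        kept, _ = quality_filter(reads, math.inf)
        assert len(kept) == 5

    def test_length_bounds(self):
        kept, stats = quality_filter(
            [read("short", "ACGT"), read("ok", "ACGT" * 30)],
            math.inf, min_len=50,
        )
        assert [r.id for r in kept] == ["ok"]
        assert stats["dropped_length"] == 1

    def test_fasta_reads_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            quality_filter([SequenceRecord("r", "ACGT")], 1.0)


class TestAnchor:
    def test_trims_primer_footprint(self):
        rng = np.random.default_rng(2)
        tail = random_seq(rng, 50)
        site = TILS_F.sequence.replace("Y", "C")
        reads = [read("r1", site + tail), read("r2", random_seq(rng, 80))]
        kept, stats = anchor_on_primer(reads, TILS_F)
        assert [r.id for r in kept] == ["r1"]
        assert kept[0].residues == tail
        assert stats["dropped_unanchored"] == 1


class TestDereplicate:
    def test_abundance_and_order(self):
        reads = [read("r1", "AAAA"), read("r2", "AAAA"), read("r3", "CCCC")]
        uniq = dereplicate(reads)
        assert [(u.sequence, u.abundance) for u in uniq] == [
            ("AAAA", 2), ("CCCC", 1)
        ]
        assert uniq[0].read_ids == ["r1", "r2"]

    def test_all_distinct_and_conservation(self):
        rng = np.random.default_rng(3)
        reads = [read(f"r{i}", random_seq(rng, 60)) for i in range(10)]
        uniq = dereplicate(reads)
        assert all(u.abundance == 1 for u in uniq)
        assert sum(u.abundance for u in uniq) == 10

    def test_abundance_tie_breaks_lexicographic(self):
        reads = [read("r1", "TTTT"), read("r2", "AAAA")]
        uniq = dereplicate(reads)
        assert [u.sequence for u in uniq] == ["AAAA", "TTTT"]


class TestClusterGreedy:
    def test_two_planted_families(self):
        rng = np.random.default_rng(4)
        centA = random_seq(rng, 300)
        centB = mutate(rng, centA, 30)  # ~90% mutual identity
        assert sequence_identity(centA, centB) < 97
        uniques = [Unique(centA, 10, ["a0"]), Unique(centB, 8, ["b0"])]
        for i in range(3):
            uniques.append(Unique(mutate(rng, centA, 3), 2, [f"a{i+1}"]))
            uniques.append(Unique(mutate(rng, centB, 3), 2, [f"b{i+1}"]))
        # brute-force all-vs-all: no cross-family pair reaches 97
        a_family = [u.sequence for u in uniques if
                    sequence_identity(u.sequence, centA) >= 97]
        b_family = [u.sequence for u in uniques if
                    sequence_identity(u.sequence, centB) >= 97]
        assert len(a_family) == 4 and len(b_family) == 4
        assert not (set(a_family) & set(b_family))
        clusters = cluster_greedy(uniques, 97.0)
        assert len(clusters) == 2
        assert {c.member_count for c in clusters} == {16, 14}

    def test_tight_family_single_otu(self):
        rng = np.random.default_rng(5)
        cent = random_seq(rng, 300)
        uniques = [Unique(cent, 5, [])] + [
            Unique(mutate(rng, cent, 2), 1, []) for _ in range(5)
        ]
        assert len(cluster_greedy(uniques, 97.0)) == 1

    def test_threshold_100_one_otu_per_unique(self):
        rng = np.random.default_rng(6)
        cent = random_seq(rng, 200)
        uniques = [Unique(cent, 3, []), Unique(mutate(rng, cent, 1), 1, [])]
        assert len(cluster_greedy(uniques, 100.0)) == 2

    def test_empty_input(self):
        assert cluster_greedy([], 97.0) == []


class TestScreenChimeras:
    @pytest.fixture()
    def parents(self):
        rng = np.random.default_rng(7)
        A = random_seq(rng, 300)
        B = mutate(rng, A, 30)
        return A, B

    def test_constructed_splice_flagged(self, parents):
        A, B = parents
        chimera = A[:150] + B[150:]
        uniques = [Unique(A, 20, []), Unique(B, 18, []),
                   Unique(chimera, 1, [])]
        kept, flagged = screen_chimeras(uniques)
        assert [u.sequence for u in flagged] == [chimera]
        assert {u.sequence for u in kept} == {A, B}

    def test_parents_never_flagged(self, parents):
        A, B = parents
        uniques = [Unique(A, 20, []), Unique(B, 18, [])]
        kept, flagged = screen_chimeras(uniques)
        assert flagged == [] and len(kept) == 2

    def test_single_eligible_parent_insufficient(self, parents):
        A, B = parents
        chimera = A[:150] + B[150:]
        # B is low-abundance: not an eligible parent
        uniques = [Unique(A, 20, []), Unique(chimera, 5, []),
                   Unique(B, 1, [])]
        kept, flagged = screen_chimeras(uniques)
        assert flagged == []

    def test_true_biological_variant_kept(self, parents):
        A, B = parents
        rng = np.random.default_rng(8)
        variant = mutate(rng, A, 2)  # 99.3% to A: one parent explains it
        uniques = [Unique(A, 20, []), Unique(B, 18, []),
                   Unique(variant, 1, [])]
        kept, flagged = screen_chimeras(uniques)
        assert flagged == []


class TestMapReads:
    @pytest.fixture()
    def centroids(self):
        rng = np.random.default_rng(9)
        a = random_seq(rng, 300)
        b = mutate(rng, a, 30)
        return [
            OtuCluster("OTU1", SequenceRecord("OTU1", a), 1),
            OtuCluster("OTU2", SequenceRecord("OTU2", b), 1),
        ], a, b

    def test_exact_reads_map_to_their_centroid(self, centroids):
        otus, a, b = centroids
        table, unmapped, assign = map_reads(
            [read("r1", a), read("r2", b), read("r3", a)], otus, 97.0
        )
        assert unmapped == 0
        counts = dict(zip(table["otu_id"], table["member_count"]))
        assert counts == {"OTU1": 2, "OTU2": 1}

    def test_distant_read_unmapped(self, centroids):
        otus, a, _ = centroids
        rng = np.random.default_rng(10)
        far = mutate(rng, a, 15)  # 95% to OTU1
        table, unmapped, _ = map_reads([read("rx", far)], otus, 97.0)
        assert unmapped == 1
        assert table["member_count"].sum() == 0

    def test_tie_goes_to_earlier_otu(self):
        cent = "ACGTACGT" * 40
        otus = [
            OtuCluster("OTU1", SequenceRecord("OTU1", cent), 1),
            OtuCluster("OTU2", SequenceRecord("OTU2", cent), 1),
        ]
        _, _, assign = map_reads([read("r", cent)], otus, 97.0)
        assert assign["r"] == "OTU1"


class TestAssignTaxonomy:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(11)
        a = random_seq(rng, 400)
        b = mutate(rng, a, 60)
        return [
            SequenceRecord("refA", a, description="species=Alpha_one"),
            SequenceRecord("refB", b, description="species=Beta_two"),
        ], a, b

    def test_identical_centroid_assigned(self, reference):
        refs, a, _ = reference
        otu = OtuCluster("OTU1", SequenceRecord("OTU1", a), 5)
        (tax,) = assign_taxonomy([otu], refs, marker="tils")
        assert tax.call == "assigned-to-species"
        assert tax.identity_pct == 100.0
        assert tax.species == "Alpha one"

    def test_below_threshold_is_novel(self, reference):
        refs, a, _ = reference
        rng = np.random.default_rng(12)
        far = mutate(rng, a, 40)  # ~90% < 91.85 tils threshold
        otu = OtuCluster("OTU1", SequenceRecord("OTU1", far), 5)
        (tax,) = assign_taxonomy([otu], refs, marker="tils")
        assert tax.identity_pct < 91.85
        assert tax.call == "novel-species-level"

    def test_cross_species_tie_is_ambiguous(self):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 400)
        refs = [
            SequenceRecord("r1", mutate(rng, seq, 4),
                           description="species=One"),
            SequenceRecord("r2", mutate(rng, seq, 4),
                           description="species=Two"),
        ]
        otu = OtuCluster("OTU1", SequenceRecord("OTU1", seq), 1)
        (tax,) = assign_taxonomy([otu], refs, marker="tils")
        assert tax.call == "ambiguous"

    def test_unlabelled_reference_rejected(self):
        refs = [SequenceRecord("r1", "ACGT" * 100)]
        otu = OtuCluster("OTU1", SequenceRecord("OTU1", "ACGT" * 100), 1)
        with pytest.raises(ValueError, match="species="):
            assign_taxonomy([otu], refs)

    def test_unknown_marker_rejected(self, reference):
        refs, a, _ = reference
        otu = OtuCluster("OTU1", SequenceRecord("OTU1", a), 1)
        with pytest.raises(ValueError):
            assign_taxonomy([otu], refs, marker="gyrB")


class TestEndToEnd:
    def test_read_conservation(self, balanced4):
        """Every input read lands in exactly one pipeline bin."""
        _, _, reads, reference = balanced4
        result = profile(reads, reference, fwd_primer=TILS_F, marker="tils")
        counts = result.stage_counts
        binned = (counts["dropped_quality"] + counts["dropped_length"]
                  + counts["dropped_unanchored"]
                  + counts["low_abundance_reads"] + counts["chimeric_reads"]
                  + counts["mapped_reads"] + counts["unmapped_reads"])
        assert binned == counts["input_reads"] == len(reads)

    def test_four_species_recovered(self, balanced4):
        _, _, reads, reference = balanced4
        result = profile(reads, reference, fwd_primer=TILS_F, marker="tils")
        assert len(result.otus) == 4
        assert sorted(t.species for t in result.taxonomy) == [
            "Species A", "Species B", "Species C", "Species D"
        ]
        assert all(t.call == "assigned-to-species" for t in result.taxonomy)

    def test_deterministic_across_read_order(self, balanced4):
        _, _, reads, reference = balanced4
        r1 = profile(reads, reference, fwd_primer=TILS_F)
        r2 = profile(list(reversed(reads)), reference, fwd_primer=TILS_F)
        c1 = sorted(c.centroid.residues for c in r1.otus)
        c2 = sorted(c.centroid.residues for c in r2.otus)
        assert c1 == c2
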