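"""Primer matching, in-silico PCR and gene regions.

The primer-matching oracle is a plain sliding-window scan written
independently of the bit-vector implementation.
"""

import numpy as np
import pytest

from thiomarker.markers import (
    DegeneratePrimer,
    GeneRegion,
    MarkerNotFoundError,
    PRIMER_SETS,
    TILS_F,
    TILS_R,
    extract_region,
    insilico_pcr,
    locate_marker,
    match_primer,
    revcomp,
)
from thiomarker.seqio import IUPAC_SETS, SequenceRecord

from conftest import random_seq


def oracle_scan(primer: str, target: str, max_mm: int):
    """Sliding-window mismatch count on both strands; 3' terminal 3
    bases must match exactly (IUPAC sets intersecting = match)."""
    def compatible(p, t):
        return not IUPAC_SETS[p].isdisjoint(IUPAC_SETS[t])

    hits = []
    L = len(primer)
    for pattern, strand, tail in ((primer, "+", range(L - 3, L)),
                                  (revcomp(primer), "-", range(0, 3))):
        for off in range(len(target) - L + 1):
            mm = sum(not compatible(pattern[i], target[off + i])
                     for i in range(L))
            tail_mm = sum(not compatible(pattern[i], target[off + i])
                          for i in tail)
            if mm <= max_mm and tail_mm == 0:
                hits.append((off, strand, mm))
    return sorted(hits)


class TestMatchPrimer:
    def test_exact_planted_site(self):
        hits = match_primer(DegeneratePrimer("p", "ACGTACGTAC", 0),
                            SequenceRecord("t", "TTACGTACGTACTT"))
        assert [(h.position, h.strand, h.mismatches) for h in hits] == [
            (2, "+", 0)
        ]

    def test_degenerate_primer_zero_mismatches(self):
        # Y = {C,T}: a site realising both Y positions as C matches exactly
        site = TILS_F.sequence.replace("Y", "C")
        rng = np.random.default_rng(1)
        target = SequenceRecord("t", random_seq(rng, 50) + site + random_seq(rng, 50))
        hits = match_primer(TILS_F, target)
        assert hits and hits[0].position == 50 and hits[0].mismatches == 0

    def test_agrees_with_sliding_window_oracle(self):
        rng = np.random.default_rng(23)
        iupac = list("ACGT") + list("RYSWKM")
        for trial in range(8):
            primer_seq = "".join(
                rng.choice(iupac if rng.random() < 0.3 else list("ACGT"))
                for _ in range(12)
            )
            target = random_seq(rng, 400)
            # plant a 1-mismatch copy to guarantee some signal
            pos = int(rng.integers(0, 388))
            realised = "".join(
                sorted(IUPAC_SETS[c])[0] for c in primer_seq
            )
            corrupted = list(realised)
            corrupted[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupted[5]]
            target = target[:pos] + "".join(corrupted) + target[pos + 12:]
            primer = DegeneratePrimer("p", primer_seq, 2)
            got = sorted(
                (h.position, h.strand, h.mismatches)
                for h in match_primer(primer, SequenceRecord("t", target))
            )
            assert got == oracle_scan(primer.sequence, target, 2), trial

    def test_three_prime_mismatch_disallowed(self):
        primer = DegeneratePrimer("p", "ACGTACGTAC", 2)
        target = "TT" + "ACGTACGTAT" + "TT"  # mismatch at the 3' base
        assert all(
            h.strand == "-" or h.position != 2
            for h in match_primer(primer, SequenceRecord("t", target))
        )

    def test_n_in_target_matches_anything(self):
        primer = DegeneratePrimer("p", "ACGTACGTAC", 0)
        hits = match_primer(primer, SequenceRecord("t", "TTACGTACNTACTT"))
        assert hits and hits[0].mismatches == 0


class TestInsilicoPcr:
    @pytest.fixture()
    def template_619(self):
        rng = np.random.default_rng(5)
        fwd_site = TILS_F.sequence.replace("Y", "C")
        rev_site = revcomp(TILS_R.sequence.replace("M", "A").replace("Y", "T"))
        core = random_seq(rng, 619 - len(fwd_site) - len(rev_site))
        return SequenceRecord(
            "tmpl", random_seq(rng, 100) + fwd_site + core + rev_site
            + random_seq(rng, 80)
        )

    def test_planted_product_length(self, template_619):
        products = insilico_pcr(TILS_F, TILS_R, template_619)
        assert len(products) == 1
        assert len(products[0]) == 619
        assert (products[0].start, products[0].end) == (100, 719)

    def test_reverse_strand_template(self, template_619):
        flipped = SequenceRecord("flip", revcomp(template_619.residues))
        products = insilico_pcr(TILS_F, TILS_R, flipped)
        assert len(products) == 1
        assert products[0].strand == "-"
        assert products[0].sequence == insilico_pcr(
            TILS_F, TILS_R, template_619
        )[0].sequence

    def test_missing_reverse_site_yields_nothing(self):
        rng = np.random.default_rng(6)
        fwd_site = TILS_F.sequence.replace("Y", "C")
        tmpl = SequenceRecord("t", random_seq(rng, 50) + fwd_site
                              + random_seq(rng, 600))
        assert insilico_pcr(TILS_F, TILS_R, tmpl) == []

    def test_length_bounds_enforced(self, template_619):
        assert insilico_pcr(TILS_F, TILS_R, template_619,
                            min_len=700, max_len=2000) == []

    def test_packaged_primer_set(self):
        fwd, rev = PRIMER_SETS["tils_v1"]
        assert fwd.sequence == "CGCATCAYCAGAAYGATCAGGC"
        assert rev.sequence == "TMTYCCACACCAACACCTGCT"


class TestRegions:
    def test_tils_region_lengths(self):
        rng = np.random.default_rng(7)
        gene = SequenceRecord("tils", random_seq(rng, 1100))
        assert len(extract_region(gene, 420, 1003)) == 584
        assert len(extract_region(gene, 596, 956)) == 361

    def test_rpob_region_length(self):
        rng = np.random.default_rng(8)
        gene = SequenceRecord("rpob", random_seq(rng, 4000))
        assert len(extract_region(gene, 481, 836)) == 356

    def test_identity_slice(self):
        rng = np.random.default_rng(9)
        gene = SequenceRecord("g", random_seq(rng, 300))
        region = extract_region(gene, 1, 300)
        assert region.sequence == gene.residues

    @pytest.mark.parametrize("start,end", [(0, 10), (5, 4), (1, 301)])
    def test_out_of_range_rejected(self, start, end):
        gene = SequenceRecord("g", "ACGT" * 75)
        with pytest.raises(ValueError):
            extract_region(gene, start, end)

    def test_region_vs_whole_gene_identity_within_3_points(self, clade):
        """Sub-region identity tracks whole-gene identity closely."""
        from thiomarker.pairwise import sequence_identity

        _, _, truth = clade
        genes = truth.markers["tils_like"].genes
        labels = sorted(genes)[:5]
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                whole = sequence_identity(genes[a], genes[b])
                ra = extract_region(genes[a], 420, 1003).sequence
                rb = extract_region(genes[b], 420, 1003).sequence
                region = sequence_identity(ra, rb)
                assert abs(whole - region) <= 3.0, (a, b, whole, region)


class TestLocateMarker:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(10)
        ref = SequenceRecord("ref", random_seq(rng, 1300))
        genome = SequenceRecord(
            "chr", random_seq(rng, 5000) + ref.residues + random_seq(rng, 4000)
        )
        return ref, genome

    def test_exact_copy_found(self, planted):
        ref, genome = planted
        region = locate_marker(genome, ref)
        assert region.sequence == ref.residues
        assert (region.start_1based, region.end_1based) == (5001, 6300)
        assert region.identity_pct == 100.0

    def test_reverse_strand_copy(self, planted):
        ref, _ = planted
        rng = np.random.default_rng(11)
        genome = SequenceRecord(
            "chr2",
            random_seq(rng, 3000) + revcomp(ref.residues) + random_seq(rng, 2000),
        )
        region = locate_marker(genome, ref)
        assert region.strand == "-"
        assert region.sequence == ref.residues
        assert (region.start_1based, region.end_1based) == (3001, 4300)

    def test_absent_marker_raises(self, planted):
        ref, _ = planted
        rng = np.random.default_rng(12)
        with pytest.raises(MarkerNotFoundError):
            locate_marker(SequenceRecord("r", random_seq(rng, 8000)), ref)
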