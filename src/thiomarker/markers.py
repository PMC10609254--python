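"""Degenerate-primer matching, in-silico PCR and marker-gene regions.

A degenerate primer is an IUPAC string (e.g. ``Y`` = C/T, ``M`` = A/C);
a primer base matches a target base when their IUPAC sets intersect, so
an ``N`` in an assembly never produces a false negative. Mismatch
tolerance follows PCR chemistry: by default up to ``max_mismatches``
anywhere except the 3' terminal 3 bases, which must match exactly (a 3'
mismatch aborts extension).

The packaged primer set ``tils_v1`` amplifies a ~619 bp fragment of the
tilS gene (tRNA(Ile)-lysidine synthase), the marker used for
species-level amplicon profiling of *Thiothrix* communities:

* TilS_F ``CGCATCAYCAGAAYGATCAGGC``
* TilS_R ``TMTYCCACACCAACACCTGCT``

User-facing gene-region coordinates (e.g. tilS 420-1003, rpoB 481-836)
are 1-based inclusive, the convention of the wet-lab literature; all
internal coordinates are 0-based half-open and conversion happens only
at this interface.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import pairwise
from .seqio import IUPAC_SETS, SequenceRecord

#: 3' bases that must match exactly
THREE_PRIME_EXACT = 3
DEFAULT_MAX_MISMATCHES = 2

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}


def _bitmask(base: str) -> int:
    return sum(_BITS[b] for b in IUPAC_SETS[base])


_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC primer with a mismatch budget."""

    name: str
    sequence: str
    max_mismatches: int = DEFAULT_MAX_MISMATCHES

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r}: shorter than 10 nt")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


TILS_F = DegeneratePrimer("TilS_F", "CGCATCAYCAGAAYGATCAGGC")
TILS_R = DegeneratePrimer("TilS_R", "TMTYCCACACCAACACCTGCT")

PRIMER_SETS: dict[str, tuple[DegeneratePrimer, DegeneratePrimer]] = {
    "tils_v1": (TILS_F, TILS_R),
}


@dataclass(frozen=True)
class PrimerMatch:
    position: int  # 0-based start of the footprint on the forward strand
    strand: str  # '+' or '-'
    mismatches: int


def _scan_oriented(pattern: str, target_bits: np.ndarray,
                   exact_tail: str, max_mismatches: int) -> list[tuple[int, int]]:
    """Positions where ``pattern`` matches the forward-strand bit array.

    ``exact_tail`` selects which end of the *pattern* carries the 3'
    zone: 'right' for a plus-strand primer, 'left' for the
    reverse-complemented pattern of a minus-strand primer.
    """
    L = len(pattern)
    n = len(target_bits)
    if n < L:
        return []
    n_off = n - L + 1
    mism = np.zeros(n_off, dtype=np.int32)
    tail_mism = np.zeros(n_off, dtype=np.int32)
    if exact_tail == "right":
        tail_idx = range(L - THREE_PRIME_EXACT, L)
    else:
        tail_idx = range(0, THREE_PRIME_EXACT)
    tail_set = set(tail_idx)
    for i, base in enumerate(pattern):
        pm = _bitmask(base)
        incompat = (target_bits[i : i + n_off] & pm) == 0
        mism += incompat
        if i in tail_set:
            tail_mism += incompat
    ok = (tail_mism == 0) & (mism <= max_mismatches)
    return [(int(p), int(mism[p])) for p in np.nonzero(ok)[0]]


def _target_bits(target: SequenceRecord | str) -> np.ndarray:
    seq = target.residues if isinstance(target, SequenceRecord) else target.upper()
    lut = np.zeros(256, dtype=np.uint8)
    for base in IUPAC_SETS:
        lut[ord(base)] = _bitmask(base)
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def match_primer(
    primer: DegeneratePrimer, target: SequenceRecord | str,
    max_mismatches: int | None = None,
) -> list[PrimerMatch]:
    """All annealing sites of ``primer`` on both strands of ``target``.

    Positions are 0-based starts of the footprint on the forward strand,
    sorted by position. The 3' terminal bases must match exactly.
    """
    mm = primer.max_mismatches if max_mismatches is None else max_mismatches
    bits = _target_bits(target)
    hits: list[PrimerMatch] = []
    for pos, m in _scan_oriented(primer.sequence, bits, "right", mm):
        hits.append(PrimerMatch(pos, "+", m))
    # a minus-strand primer appears on the forward strand as its
    # reverse complement, with the 3' end at the *left* of the footprint
    for pos, m in _scan_oriented(revcomp(primer.sequence), bits, "left", mm):
        hits.append(PrimerMatch(pos, "-", m))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass
class Amplicon:
    """An in-silico PCR product, including both primer footprints."""

    source_id: str
    start: int  # 0-based half-open on the forward strand of the source
    end: int
    strand: str  # strand of the product (the forward primer's strand)
    sequence: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid amplicon coordinates")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence length != end - start")

    def __len__(self) -> int:
        return len(self.sequence)


def insilico_pcr(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    templates: Sequence[SequenceRecord] | SequenceRecord,
    min_len: int = 200,
    max_len: int = 2000,
) -> list[Amplicon]:
    """Enumerate PCR products of a primer pair over template sequences.

    Every compatible (forward site, downstream reverse site) pair with a
    product length inside ``[min_len, max_len]`` is reported — no "best
    product" heuristic; downstream dereplication handles multiples. The
    product is reported on the forward primer's strand. Zero products is
    a valid outcome.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    if isinstance(templates, SequenceRecord):
        templates = [templates]
    products: list[Amplicon] = []
    for tmpl in templates:
        fhits = match_primer(fwd, tmpl)
        rhits = match_primer(rev, tmpl)
        # orientation 1: fwd on '+', rev on '-' downstream
        for fh in (h for h in fhits if h.strand == "+"):
            for rh in (h for h in rhits if h.strand == "-"):
                end = rh.position + len(rev)
                length = end - fh.position
                if min_len <= length <= max_len:
                    products.append(Amplicon(
                        tmpl.id, fh.position, end, "+",
                        tmpl.residues[fh.position : end],
                    ))
        # orientation 2: fwd on '-', rev on '+' upstream; product read on '-'
        for fh in (h for h in fhits if h.strand == "-"):
            for rh in (h for h in rhits if h.strand == "+"):
                end = fh.position + len(fwd)
                length = end - rh.position
                if min_len <= length <= max_len:
                    products.append(Amplicon(
                        tmpl.id, rh.position, end, "-",
                        revcomp(tmpl.residues[rh.position : end]),
                    ))
    products.sort(key=lambda a: (a.source_id, a.start, a.end, a.strand))
    return products


@dataclass
class GeneRegion:
    """A 1-based inclusive slice of a gene (or a located gene copy)."""

    gene_id: str
    start_1based: int
    end_1based: int
    sequence: str
    strand: str = "+"
    identity_pct: float = 100.0

    def __post_init__(self) -> None:
        if not (1 <= self.start_1based <= self.end_1based):
            raise ValueError("invalid 1-based region coordinates")
        if len(self.sequence) != self.end_1based - self.start_1based + 1:
            raise ValueError("region length != end - start + 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(
            id=f"{self.gene_id}_{self.start_1based}_{self.end_1based}",
            residues=self.sequence,
        )


class MarkerNotFoundError(LookupError):
    pass


def extract_region(
    gene: SequenceRecord, start_1based: int, end_1based: int
) -> GeneRegion:
    """Inclusive 1-based sub-region of a gene (tilS 420-1003 style)."""
    if not (1 <= start_1based <= end_1based <= len(gene)):
        raise ValueError(
            f"region {start_1based}-{end_1based} out of range for "
            f"{gene.id!r} (length {len(gene)})"
        )
    return GeneRegion(
        gene_id=gene.id,
        start_1based=start_1based,
        end_1based=end_1based,
        sequence=gene.residues[start_1based - 1 : end_1based],
    )


def locate_marker(
    genome: Sequence[SequenceRecord] | SequenceRecord,
    reference_gene: SequenceRecord,
    min_identity: float = 70.0,
    seed_k: int = 15,
) -> GeneRegion:
    """Find the copy of a reference gene in an unannotated assembly.

    Seed-and-extend: exact ``seed_k``-mers of the reference vote for a
    diagonal on each strand of each contig; the densest diagonal band is
    aligned in full (semi-global) and the genome subsequence covering
    the reference span is returned, reverse-complemented when the hit is
    on the minus strand. Fails when the best identity is below
    ``min_identity``.
    """
    if len(reference_gene) > 10_000:
        raise ValueError("reference gene longer than 10 kb")
    contigs = [genome] if isinstance(genome, SequenceRecord) else list(genome)
    ref = reference_gene.residues
    ref_kmers: dict[str, list[int]] = defaultdict(list)
    for i in range(len(ref) - seed_k + 1):
        ref_kmers[ref[i : i + seed_k]].append(i)

    best: tuple[float, GeneRegion] | None = None
    for contig in contigs:
        for strand in ("+", "-"):
            seq = contig.residues if strand == "+" else revcomp(contig.residues)
            diags: dict[int, int] = defaultdict(int)
            for j in range(len(seq) - seed_k + 1):
                for i in ref_kmers.get(seq[j : j + seed_k], ()):
                    diags[(j - i) // 50] += 1  # banded diagonal bins
            if not diags:
                continue
            band = max(sorted(diags), key=lambda d: diags[d])
            approx = band * 50
            pad = max(50, len(ref) // 10)
            w0 = max(0, approx - pad)
            w1 = min(len(seq), approx + len(ref) + pad)
            window = seq[w0:w1]
            if not window:
                continue
            res = pairwise.global_align(ref, window)
            # genome span covered by the reference within the window
            s, e = res.internal_start, res.internal_end
            win_off = res.aligned_b[:s].replace("-", "")
            win_len = len(res.aligned_b[s:e].replace("-", ""))
            g0 = w0 + len(win_off)
            g1 = g0 + win_len
            if strand == "-":
                g0, g1 = len(contig) - g1, len(contig) - g0
            region = GeneRegion(
                gene_id=f"{contig.id}|{reference_gene.id}",
                start_1based=g0 + 1,
                end_1based=g1,
                sequence=window[len(win_off) : len(win_off) + win_len],
                strand=strand,
                identity_pct=res.identity_pct,
            )
            if best is None or res.identity_pct > best[0]:
                best = (res.identity_pct, region)
    if best is None or best[0] < min_identity:
        got = f"{best[0]:.1f}%" if best else "no seed hits"
        raise MarkerNotFoundError(
            f"marker {reference_gene.id!r} not found (best: {got}, "
            f"required {min_identity}%)"
        )
    return best[1]
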