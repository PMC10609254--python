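"""Fragment-based average nucleotide identity (ANI).

Both genomes are cut into consecutive non-overlapping 1020 bp fragments
(the OrthoANI convention; trailing remainders are discarded). Every
fragment of one genome is matched against the fragments of the other on
both strands via exact 15-mer seeding followed by full semi-global
dynamic programming on the seeded candidates. Reciprocal best-hit (RBH)
fragment pairs with aligned coverage >= ``min_coverage`` on both
fragments are kept, and ANI is the mean percent identity over the kept
pairs.

The procedure is symmetric by construction: the two genomes are ordered
canonically (by id) before matching, so ``ani(a, b) == ani(b, a)``
exactly. A pair with no RBH fragments has *undefined* ANI — an explicit
error, never 0 — because 0 would corrupt species-threshold logic
downstream.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import pairwise
from .pairwise import IdentityMatrix, Scoring, DEFAULT_SCORING
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_LEN = 1020
DEFAULT_MIN_COVERAGE = 0.35
SEED_K = 15
#: candidates (per strand) taken forward to full DP, ranked by seed count
MAX_CANDIDATES = 4


class AniUndefinedError(ValueError):
    """No reciprocal-best-hit fragment pairs: genomes too divergent."""


@dataclass(frozen=True)
class Fragment:
    contig_id: str
    start: int  # 0-based half-open on the contig
    end: int
    seq: str


@dataclass
class AniEstimate:
    genome_a: str
    genome_b: str
    ani_pct: float
    n_fragments_a: int
    n_fragments_b: int
    n_rbh: int
    mean_coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ani_pct <= 100.0):
            raise ValueError("ani_pct outside [0, 100]")
        if self.n_rbh > min(self.n_fragments_a, self.n_fragments_b):
            raise ValueError("more RBH pairs than fragments")


def fragment_genome(
    contigs: Sequence[SequenceRecord] | SequenceRecord,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
) -> list[Fragment]:
    """Cut each contig into consecutive windows of ``fragment_len``."""
    if fragment_len < 100:
        raise ValueError("fragment_len must be >= 100")
    if isinstance(contigs, SequenceRecord):
        contigs = [contigs]
    frags: list[Fragment] = []
    for contig in contigs:
        n_full = len(contig) // fragment_len
        for i in range(n_full):
            s = i * fragment_len
            frags.append(
                Fragment(contig.id, s, s + fragment_len,
                         contig.residues[s : s + fragment_len])
            )
    if not frags:
        warnings.warn(
            "no fragments produced: every contig shorter than "
            f"{fragment_len} bp", stacklevel=2
        )
    return frags


_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class _FragmentMatcher:
    """Seeded best-hit search between two fragment sets."""

    def __init__(self, frags_a: list[Fragment], frags_b: list[Fragment],
                 scoring: Scoring):
        self.fa = frags_a
        self.fb = frags_b
        self.scoring = scoring
        self.index: dict[str, list[int]] = defaultdict(list)
        for j, f in enumerate(frags_b):
            for km in _kmers(f.seq, SEED_K):
                self.index[km].append(j)
        # alignment cache keyed by (i, j, strand)
        self._aln: dict[tuple[int, int, int], tuple[float, float, float]] = {}

    def _candidates(self, seq: str) -> list[tuple[int, int]]:
        counts: dict[int, int] = defaultdict(int)
        for km in _kmers(seq, SEED_K):
            for j in self.index.get(km, ()):
                counts[j] += 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:MAX_CANDIDATES]

    def _align(self, i: int, j: int, strand: int) -> tuple[float, float, float]:
        """(score, identity_pct, coverage) for fragment pair (i, j)."""
        key = (i, j, strand)
        if key not in self._aln:
            a = self.fa[i].seq
            b = self.fb[j].seq if strand > 0 else _revcomp(self.fb[j].seq)
            res = pairwise.global_align(a, b, scoring=self.scoring)
            s, e = res.internal_start, res.internal_end
            cov_a = sum(1 for c in res.aligned_a[s:e] if c != "-") / len(a)
            cov_b = sum(1 for c in res.aligned_b[s:e] if c != "-") / len(b)
            self._aln[key] = (res.score, res.identity_pct, min(cov_a, cov_b))
        return self._aln[key]

    def best_hits_of_a(self) -> dict[int, tuple[int, int]]:
        """fragment index in A -> (best fragment index in B, strand)."""
        best: dict[int, tuple[int, int]] = {}
        for i, frag in enumerate(self.fa):
            entries = []  # (-score, j, -strand) for deterministic ordering
            for strand, seq in ((1, frag.seq), (-1, _revcomp(frag.seq))):
                for j, _ in self._candidates(seq):
                    score, _, _ = self._align(i, j, strand)
                    entries.append((-score, j, -strand))
            if entries:
                _, j, nstrand = min(entries)
                best[i] = (j, -nstrand)
        return best

    def best_hits_of_b(self) -> dict[int, tuple[int, int]]:
        """fragment index in B -> (best fragment index in A, strand).

        Reuses the cached alignments: alignment of (i, j) serves both
        directions, so only candidate pairs never seen from the A side
        trigger new DP.
        """
        rindex: dict[str, list[int]] = defaultdict(list)
        for i, f in enumerate(self.fa):
            for km in _kmers(f.seq, SEED_K):
                rindex[km].append(i)
        best: dict[int, tuple[int, int]] = {}
        for j, frag in enumerate(self.fb):
            entries = []
            for strand, seq in ((1, frag.seq), (-1, _revcomp(frag.seq))):
                counts: dict[int, int] = defaultdict(int)
                for km in _kmers(seq, SEED_K):
                    for i in rindex.get(km, ()):
                        counts[i] += 1
                ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
                for i, _ in ranked[:MAX_CANDIDATES]:
                    score, _, _ = self._align(i, j, strand)
                    entries.append((-score, i, -strand))
            if entries:
                _, i, nstrand = min(entries)
                best[j] = (i, -nstrand)
        return best


def compute_ani(
    genome_a: Sequence[SequenceRecord] | SequenceRecord,
    genome_b: Sequence[SequenceRecord] | SequenceRecord,
    genome_a_id: str | None = None,
    genome_b_id: str | None = None,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: Scoring = DEFAULT_SCORING,
) -> AniEstimate:
    """Reciprocal-best-hit fragment ANI between two genomes."""
    ga = [genome_a] if isinstance(genome_a, SequenceRecord) else list(genome_a)
    gb = [genome_b] if isinstance(genome_b, SequenceRecord) else list(genome_b)
    id_a = genome_a_id or ga[0].id
    id_b = genome_b_id or gb[0].id

    # canonical ordering makes the procedure independent of argument order
    swapped = id_b < id_a
    (g1, n1), (g2, n2) = sorted(
        [(ga, id_a), (gb, id_b)], key=lambda t: t[1]
    )
    f1 = fragment_genome(g1, fragment_len)
    f2 = fragment_genome(g2, fragment_len)
    if not f1 or not f2:
        raise AniUndefinedError(
            f"ANI undefined for ({id_a}, {id_b}): a genome yields no fragments"
        )
    matcher = _FragmentMatcher(f1, f2, scoring)
    best_12 = matcher.best_hits_of_a()
    best_21 = matcher.best_hits_of_b()

    idents: list[float] = []
    covs: list[float] = []
    for i, (j, strand) in sorted(best_12.items()):
        back = best_21.get(j)
        if back is None or back[0] != i:
            continue
        _, ident, cov = matcher._align(i, j, strand)
        if cov >= min_coverage:
            idents.append(ident)
            covs.append(cov)
    if not idents:
        raise AniUndefinedError(
            f"ANI undefined for ({id_a}, {id_b}): no reciprocal best-hit "
            "fragment pairs above coverage"
        )
    n_rbh = len(idents)
    nf = {n1: len(f1), n2: len(f2)}
    return AniEstimate(
        genome_a=id_a,
        genome_b=id_b,
        ani_pct=float(np.mean(idents)),
        n_fragments_a=nf[id_a],
        n_fragments_b=nf[id_b],
        n_rbh=n_rbh,
        mean_coverage=float(np.mean(covs)),
    )


def ani_matrix(
    genomes: Mapping[str, Sequence[SequenceRecord]],
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    scoring: Scoring = DEFAULT_SCORING,
) -> IdentityMatrix:
    """Symmetric ANI matrix; undefined pairs become NaN cells (logged)."""
    ids = list(genomes)
    if len(ids) < 2:
        raise ValueError("need at least two genomes")
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = compute_ani(
                    genomes[ids[i]], genomes[ids[j]],
                    genome_a_id=ids[i], genome_b_id=ids[j],
                    fragment_len=fragment_len, min_coverage=min_coverage,
                    scoring=scoring,
                )
                vals[i, j] = vals[j, i] = est.ani_pct
            except AniUndefinedError:
                logger.warning("ANI undefined for (%s, %s); cell flagged NA",
                               ids[i], ids[j])
                vals[i, j] = vals[j, i] = np.nan
    return IdentityMatrix(ids, vals)
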