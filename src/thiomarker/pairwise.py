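"""Pairwise alignment, percent identity and Kimura 2-parameter distances.

Identity here means the fraction of matching columns in an optimal
semi-global alignment: Needleman-Wunsch with affine gap costs in which
terminal gaps are free. By default identity is computed over *internal*
columns only (terminal-gap columns excluded), so a gene region compared
against a full gene is scored on the overlap, not penalised for being
shorter. Degenerate IUPAC bases count as a match when their base sets
intersect.

The K2P (K80) distance distinguishes transition (P) and transversion (Q)
proportions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

P and Q are computed over ungapped, unambiguous columns only. When the
argument of a logarithm is non-positive the distance is undefined
(saturation) and :class:`SaturationError` is raised.

The dynamic programming engine is Bio.Align.PairwiseAligner with an
IUPAC-aware substitution matrix; exhaustive enumeration of alignments is
used as the oracle in the test-suite, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import IUPAC_SETS, SequenceRecord

_ALPHABET = "ACGTNRYSWKMBDHV"

#: longest sequence global_align will accept; genome-scale comparisons
#: belong to the fragment-based ANI estimator.
MAX_ALIGN_LEN = 100_000


class SaturationError(ArithmeticError):
    """K2P distance undefined: substitution saturation."""


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring. A gap of length L costs open + extend*(L-1)."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


def bases_compatible(a: str, b: str) -> bool:
    """True when the IUPAC sets of two bases intersect."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


@lru_cache(maxsize=8)
def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for x in _ALPHABET:
        for y in _ALPHABET:
            matrix[x, y] = (
                scoring.match if bases_compatible(x, y) else scoring.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # free terminal gaps: semi-global
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass
class AlignmentResult:
    """A pairwise alignment and its identity bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    columns: int
    identity_pct: float
    internal_start: int = field(default=0)
    internal_end: int = field(default=0)  # half-open column index

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _internal_span(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """Column range [start, end) excluding terminal-gap columns."""
    def span(s: str) -> tuple[int, int]:
        first = len(s) - len(s.lstrip("-"))
        last = len(s.rstrip("-"))
        return first, last

    a0, a1 = span(aligned_a)
    b0, b1 = span(aligned_b)
    return max(a0, b0), min(a1, b1)


def _identity_stats(
    aligned_a: str, aligned_b: str, convention: str
) -> tuple[int, int, int, int]:
    if convention not in ("internal", "full"):
        raise ValueError(f"unknown identity convention {convention!r}")
    if convention == "internal":
        start, end = _internal_span(aligned_a, aligned_b)
    else:
        start, end = 0, len(aligned_a)
    matches = 0
    for x, y in zip(aligned_a[start:end], aligned_b[start:end]):
        if x != "-" and y != "-" and bases_compatible(x, y):
            matches += 1
    return matches, end - start, start, end


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
    convention: str = "internal",
) -> AlignmentResult:
    """Optimal semi-global alignment of two nucleotide sequences.

    Refuses sequences longer than :data:`MAX_ALIGN_LEN` (use the ANI
    estimator for genomes).
    """
    sa = a.residues if isinstance(a, SequenceRecord) else str(a).upper()
    sb = b.residues if isinstance(b, SequenceRecord) else str(b).upper()
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if max(len(sa), len(sb)) > MAX_ALIGN_LEN:
        raise ValueError(
            f"sequence longer than {MAX_ALIGN_LEN} bp; use the ani module "
            "for genome-scale comparisons"
        )
    aligner = _make_aligner(scoring)
    aln = aligner.align(sa, sb)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    matches, columns, start, end = _identity_stats(aligned_a, aligned_b, convention)
    if columns == 0:
        raise ValueError("alignment has no scorable columns")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        matches=matches,
        columns=columns,
        identity_pct=100.0 * matches / columns,
        internal_start=start,
        internal_end=end,
    )


def identity_pct(result: AlignmentResult, convention: str = "internal") -> float:
    """Recompute percent identity of an alignment under a convention."""
    matches, columns, _, _ = _identity_stats(
        result.aligned_a, result.aligned_b, convention
    )
    if columns == 0:
        raise ValueError("zero alignment columns under this convention")
    return 100.0 * matches / columns


def sequence_identity(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
    convention: str = "internal",
) -> float:
    """Convenience: align and return percent identity."""
    return global_align(a, b, scoring=scoring, convention=convention).identity_pct


# ---------------------------------------------------------------------------
# labelled symmetric matrices

class LabelledMatrix:
    """Symmetric labelled matrix with TSV round-trip."""

    _diag: float = 0.0

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match label count")
        finite = ~np.isnan(values)
        sym = np.isclose(
            np.where(finite, values, 0.0), np.where(finite.T, values.T, 0.0)
        )
        if not sym.all():
            raise ValueError("matrix not symmetric")
        self.labels = labels
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_tsv(self, path: str | Path, decimals: int = 2) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("\t".join([""] + self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                cells = [
                    "NA" if np.isnan(v) else f"{v:.{decimals}f}" for v in row
                ]
                fh.write("\t".join([lab] + cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelledMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln]
        labels = lines[0].split("\t")[1:]
        vals = np.full((len(labels), len(labels)), np.nan)
        for i, line in enumerate(lines[1:]):
            cells = line.split("\t")
            for j, c in enumerate(cells[1 : len(labels) + 1]):
                if c != "NA":
                    vals[i, j] = float(c)
        return cls(labels, vals)

    def __repr__(self) -> str:
        return f"{type(self).__name__}(n={len(self.labels)})"


class IdentityMatrix(LabelledMatrix):
    """Percent identities; diagonal is 100, entries in [0, 100] or NaN."""

    _diag = 100.0

    def __init__(self, labels, values):
        super().__init__(labels, values)
        finite = ~np.isnan(self.values)
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        v = self.values[finite]
        if ((v < 0) | (v > 100)).any():
            raise ValueError("identities must lie in [0, 100]")


class DistanceMatrix(LabelledMatrix):
    """K2P distances; diagonal 0, entries >= 0 or NaN (saturated)."""

    def __init__(self, labels, values):
        super().__init__(labels, values)
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be 0")
        v = self.values[~np.isnan(self.values)]
        if (v < 0).any():
            raise ValueError("distances must be non-negative")


def identity_matrix(
    records: Sequence[SequenceRecord],
    scoring: Scoring = DEFAULT_SCORING,
    convention: str = "internal",
) -> IdentityMatrix:
    """All-pairs percent identity (each unordered pair aligned once)."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = sequence_identity(
                records[i], records[j], scoring=scoring, convention=convention
            )
            vals[i, j] = vals[j, i] = pid
    return IdentityMatrix(ids, vals)


# ---------------------------------------------------------------------------
# Kimura 2-parameter

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def k2p_counts(aligned_a: str, aligned_b: str) -> tuple[int, int, int]:
    """(n_sites, transitions, transversions) over plain-ACGT columns."""
    n = ts = tv = 0
    for x, y in zip(aligned_a, aligned_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return n, ts, tv


def k2p_from_proportions(P: float, Q: float) -> float:
    """Evaluate d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined (P={P:.4f}, Q={Q:.4f}): saturation"
        )
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_distance(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
) -> float:
    """Align two sequences and return their K2P distance."""
    res = global_align(a, b, scoring=scoring)
    s, e = res.internal_start, res.internal_end
    n, ts, tv = k2p_counts(res.aligned_a[s:e], res.aligned_b[s:e])
    if n == 0:
        raise ValueError("no ungapped unambiguous columns for K2P")
    return k2p_from_proportions(ts / n, tv / n)


def k2p_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """K2P distance matrix from an equal-length (aligned) sequence set.

    Vectorised over numpy byte arrays; used by the tree and bootstrap
    machinery where thousands of replicate matrices are needed.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(
            "k2p_matrix requires equal-length (aligned) sequences; "
            f"got lengths {sorted(lengths)}"
        )
    ids = [r.id for r in records]
    arr = np.frombuffer(
        "".join(r.residues for r in records).encode(), dtype="S1"
    ).reshape(len(records), -1)
    return k2p_matrix_from_array(ids, arr)


def k2p_matrix_from_array(ids: Sequence[str], arr: np.ndarray) -> DistanceMatrix:
    """K2P matrix from an (n_seq, n_site) array of single-byte bases."""
    plain = np.isin(arr, np.array([b"A", b"C", b"G", b"T"], dtype="S1"))
    purine = np.isin(arr, np.array([b"A", b"G"], dtype="S1"))
    n = arr.shape[0]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = plain[i] & plain[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError("no comparable columns for a pair")
            diff = (arr[i] != arr[j]) & ok
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            vals[i, j] = vals[j, i] = k2p_from_proportions(ts / m, tv / m)
    return DistanceMatrix(list(ids), vals)
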