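"""Sequence and tree input/output.

All pipeline stages exchange :class:`SequenceRecord` objects and dendropy
trees. Parsing is strict: malformed input raises :class:`FormatError`
naming the offending record instead of being silently repaired.

Conventions enforced at the single ingest point:

* residues are uppercased and ``U`` is mapped to ``T``;
* only IUPAC DNA letters (``ACGTN`` plus the degeneracy codes
  ``RYSWKMBDHV``) are accepted; gap characters are rejected;
* FASTQ is 4-line Phred+33 (modern Illumina output);
* a record id is the header token up to the first whitespace, the
  remainder is the description.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

#: base sets of every IUPAC DNA code
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence (genome, gene or read).

    ``quality``, when present, holds per-base Phred scores and must have
    the same length as ``residues``.
    """

    id: str
    residues: str
    description: str = ""
    quality: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seq = self.residues.upper().replace("U", "T")
        if not seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        self.residues = seq
        if self.quality is not None and len(self.quality) != len(seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=self.residues.translate(_COMPLEMENT)[::-1],
            description=self.description,
            quality=None if self.quality is None else self.quality[::-1],
        )


def _normalize_header(header: str) -> tuple[str, str]:
    parts = header.split(None, 1)
    if not parts:
        raise FormatError("empty header line")
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving order.

    Raises :class:`FormatError` on an empty file, an empty sequence or a
    duplicate id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc = _normalize_header(header)
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {rid!r} in {path}: empty sequence")
        records.append(SequenceRecord(id=rid, residues=seq, description=desc))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence before first header")
                if "-" in line or "." in line:
                    raise FormatError(
                        f"{path}: gap characters in input FASTA (record "
                        f"{_normalize_header(header)[0]!r})"
                    )
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, wrap: int = 70
) -> None:
    """Write records as FASTA; ``wrap`` caps sequence line length."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a 4-line-per-record Phred+33 FASTQ file."""
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty FASTQ file")
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: line count {len(lines)} not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"{path}: record {i // 4 + 1} header missing '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: record {i // 4 + 1} separator missing '+'")
        rid, desc = _normalize_header(head[1:])
        if len(seq) != len(qual):
            raise FormatError(
                f"record {rid!r}: sequence/quality length mismatch "
                f"({len(seq)} vs {len(qual)})"
            )
        phred = [ord(c) - 33 for c in qual]
        if any(q < 0 for q in phred):
            raise FormatError(f"record {rid!r}: quality character below '!'")
        records.append(
            SequenceRecord(id=rid, residues=seq, description=desc, quality=phred)
        )
    return records


def write_fastq(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a Newick tree; duplicate leaf labels are rejected."""
    if isinstance(path_or_string, Path) or Path(str(path_or_string)).exists():
        text = Path(path_or_string).read_text()
    else:
        text = str(path_or_string)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels in Newick: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with branch lengths to 6 decimals."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    ).strip()
    Path(path).write_text(s + "\n")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
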