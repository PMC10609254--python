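"""Amplicon community profiling: filter, dereplicate, cluster, assign.

The pipeline mirrors the classic USEARCH-style marker-gene workflow:

1. expected-error quality filtering (keep reads with
   sum of 10^(-Q/10) <= max_expected_errors);
2. anchoring on the forward primer and trimming its footprint
   (only forward-primer-anchored reads are profiled);
3. exact dereplication with abundance bookkeeping;
4. de-novo chimera screening on the dereplicated uniques (two-parent
   breakpoint model, parents at >= 2x the candidate's abundance);
5. greedy centroid ("first match wins") OTU clustering at 97% identity;
6. mapping of all surviving reads to centroids ("best match wins");
7. threshold-based species assignment of each OTU against a labelled
   reference marker database.

Identity everywhere is the semi-global (free terminal gaps) percent
identity of the pairwise module — reads are fragments of the amplicon,
so terminal overhangs are not penalised. Every stage is deterministic;
ties are broken toward the earlier-created OTU and lexicographically
smaller sequence.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pairwise
from .markers import DegeneratePrimer, match_primer
from .pairwise import sequence_identity
from .marker_eval import PAPER_2023_THRESHOLDS
from .seqio import SequenceRecord

DEFAULT_CLUSTER_ID = 97.0
CHIMERA_SEGMENT_ID = 99.0
#: a chimera segment must cover at least this many bases to count
MIN_CHIMERA_SEGMENT = 20
PARENT_ABUNDANCE_RATIO = 2.0


# ---------------------------------------------------------------------------
# read preparation

def expected_errors(quality: Sequence[int]) -> float:
    return float(sum(10.0 ** (-q / 10.0) for q in quality))


def quality_filter(
    reads: Sequence[SequenceRecord],
    max_expected_errors: float = 1.0,
    min_len: int = 0,
    max_len: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Keep reads by expected-error and length bounds.

    Reads must carry quality; FASTA input should bypass this stage
    explicitly rather than being silently passed through.
    """
    kept: list[SequenceRecord] = []
    dropped_q = dropped_len = 0
    for read in reads:
        if read.quality is None:
            raise ValueError(
                f"read {read.id!r} has no quality scores; skip "
                "quality_filter for FASTA input"
            )
        if len(read) < min_len or (max_len is not None and len(read) > max_len):
            dropped_len += 1
            continue
        if expected_errors(read.quality) > max_expected_errors:
            dropped_q += 1
            continue
        kept.append(read)
    return kept, {
        "kept": len(kept),
        "dropped_quality": dropped_q,
        "dropped_length": dropped_len,
    }


def anchor_on_primer(
    reads: Sequence[SequenceRecord],
    primer: DegeneratePrimer,
    max_start: int = 2,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Keep reads beginning at the forward primer; trim its footprint."""
    kept: list[SequenceRecord] = []
    dropped = 0
    for read in reads:
        hit = next(
            (h for h in match_primer(primer, read)
             if h.strand == "+" and h.position <= max_start),
            None,
        )
        if hit is None:
            dropped += 1
            continue
        cut = hit.position + len(primer)
        if cut >= len(read):
            dropped += 1
            continue
        kept.append(SequenceRecord(
            id=read.id,
            residues=read.residues[cut:],
            description=read.description,
            quality=None if read.quality is None else read.quality[cut:],
        ))
    return kept, {"kept": len(kept), "dropped_unanchored": dropped}


# ---------------------------------------------------------------------------
# dereplication

@dataclass
class Unique:
    sequence: str
    abundance: int
    read_ids: list[str] = field(default_factory=list)


def dereplicate(reads: Sequence[SequenceRecord]) -> list[Unique]:
    """Exact-match dereplication, sorted by abundance desc then sequence.

    Total abundance equals the input read count.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        groups[read.residues].append(read.id)
    uniques = [Unique(seq, len(ids), ids) for seq, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


# ---------------------------------------------------------------------------
# chimera screening

def _kmer_counts(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _match_profile(candidate: str, parent: str) -> np.ndarray:
    """Boolean per-candidate-base array: does this base match the parent
    in the optimal semi-global alignment? Gapped bases count as
    mismatches."""
    res = pairwise.global_align(candidate, parent)
    out = np.zeros(len(candidate), dtype=bool)
    pos = 0
    for x, y in zip(res.aligned_a, res.aligned_b):
        if x != "-":
            out[pos] = y != "-" and pairwise.bases_compatible(x, y)
            pos += 1
    return out


def screen_chimeras(
    uniques: Sequence[Unique],
    segment_identity: float = CHIMERA_SEGMENT_ID,
    parent_ratio: float = PARENT_ABUNDANCE_RATIO,
    max_parents: int = 6,
) -> tuple[list[Unique], list[Unique]]:
    """De-novo two-parent chimera screen on dereplicated uniques.

    A candidate is flagged when some breakpoint splits it into a prefix
    matching one eligible parent and a suffix matching a *different*
    parent, each at >= ``segment_identity`` over at least
    ``MIN_CHIMERA_SEGMENT`` bases, while its full-length identity to
    every single parent is below ``segment_identity``. Parents must be
    previously kept uniques with >= ``parent_ratio`` times the
    candidate's abundance. Returns (kept, flagged).
    """
    kept: list[Unique] = []
    flagged: list[Unique] = []
    for cand in uniques:  # already abundance-sorted
        eligible = [
            u for u in kept if u.abundance >= parent_ratio * cand.abundance
        ]
        if len(eligible) < 2:
            kept.append(cand)
            continue
        ck = _kmer_counts(cand.sequence)
        eligible.sort(
            key=lambda u: (-len(ck & _kmer_counts(u.sequence)), u.sequence)
        )
        parents = eligible[:max_parents]
        profiles = [_match_profile(cand.sequence, p.sequence) for p in parents]
        L = len(cand.sequence)
        frac = segment_identity / 100.0
        if any(prof.sum() >= frac * L for prof in profiles):
            kept.append(cand)  # a single parent explains the read
            continue
        prefix = [np.concatenate([[0], np.cumsum(p)]) for p in profiles]
        is_chimera = False
        for i1, p1 in enumerate(prefix):
            for i2, p2 in enumerate(prefix):
                if i1 == i2:
                    continue
                for cut in range(MIN_CHIMERA_SEGMENT,
                                 L - MIN_CHIMERA_SEGMENT + 1):
                    if (p1[cut] >= frac * cut
                            and (p2[L] - p2[cut]) >= frac * (L - cut)):
                        is_chimera = True
                        break
                if is_chimera:
                    break
            if is_chimera:
                break
        (flagged if is_chimera else kept).append(cand)
    return kept, flagged


# ---------------------------------------------------------------------------
# clustering and mapping

@dataclass
class OtuCluster:
    otu_id: str
    centroid: SequenceRecord
    member_count: int
    members: list[str] = field(default_factory=list)


def cluster_greedy(
    uniques: Sequence[Unique], threshold: float = DEFAULT_CLUSTER_ID
) -> list[OtuCluster]:
    """UCLUST-style greedy centroid clustering.

    Uniques are visited in decreasing abundance; each joins the *first*
    centroid (in creation order) with identity >= ``threshold``,
    otherwise it founds a new centroid.
    """
    order = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    clusters: list[OtuCluster] = []
    for uniq in order:
        placed = False
        for cl in clusters:
            if sequence_identity(uniq.sequence, cl.centroid.residues) >= threshold:
                cl.member_count += uniq.abundance
                cl.members.extend(uniq.read_ids)
                placed = True
                break
        if not placed:
            otu_id = f"OTU{len(clusters) + 1}"
            clusters.append(OtuCluster(
                otu_id=otu_id,
                centroid=SequenceRecord(id=otu_id, residues=uniq.sequence),
                member_count=uniq.abundance,
                members=list(uniq.read_ids),
            ))
    return clusters


def map_reads(
    reads: Sequence[SequenceRecord],
    centroids: Sequence[OtuCluster],
    threshold: float = DEFAULT_CLUSTER_ID,
) -> tuple[pd.DataFrame, int, dict[str, str]]:
    """Assign each read to its best centroid at >= ``threshold`` identity.

    Ties go to the earlier-created OTU. Returns (abundance table,
    n_unmapped, read -> otu assignments); mapped + unmapped equals the
    input read count.
    """
    counts = {cl.otu_id: 0 for cl in centroids}
    assign: dict[str, str] = {}
    unmapped = 0
    for read in reads:
        best_id = None
        best_ident = -1.0
        for cl in centroids:
            ident = sequence_identity(read.residues, cl.centroid.residues)
            if ident > best_ident:  # strict: ties keep the earlier OTU
                best_ident = ident
                best_id = cl.otu_id
        if best_id is not None and best_ident >= threshold:
            counts[best_id] += 1
            assign[read.id] = best_id
        else:
            unmapped += 1
    total = max(1, len(reads))
    table = pd.DataFrame(
        {
            "otu_id": list(counts),
            "member_count": list(counts.values()),
            "fraction": [c / total for c in counts.values()],
        }
    )
    return table, unmapped, assign


# ---------------------------------------------------------------------------
# taxonomy

@dataclass
class TaxAssignment:
    otu_id: str
    best_ref: str
    species: str
    identity_pct: float
    call: str  # assigned-to-species | novel-species-level | ambiguous
    threshold_used: float


def _ref_species(rec: SequenceRecord) -> str:
    for token in rec.description.split():
        if token.startswith("species="):
            return token[len("species="):].replace("_", " ")
    raise ValueError(
        f"reference record {rec.id!r} lacks a 'species=...' label"
    )


def assign_taxonomy(
    otus: Sequence[OtuCluster],
    reference: Sequence[SequenceRecord],
    marker: str = "tils",
    thresholds: Mapping[str, float] = PAPER_2023_THRESHOLDS,
    ambiguity_window: float = 0.5,
) -> list[TaxAssignment]:
    """Best-hit species assignment of OTU centroids.

    An OTU is ``assigned-to-species`` when its best reference identity
    reaches the marker's species threshold, ``novel-species-level``
    below it, and ``ambiguous`` when references of two different
    species tie within ``ambiguity_window`` points of the best hit.
    """
    if not reference:
        raise ValueError("empty reference database")
    if marker not in thresholds:
        raise ValueError(f"no threshold for marker {marker!r}")
    threshold = float(thresholds[marker])
    out: list[TaxAssignment] = []
    for cl in otus:
        hits = sorted(
            (
                (sequence_identity(cl.centroid.residues, ref.residues),
                 ref.id, _ref_species(ref))
                for ref in reference
            ),
            key=lambda h: (-h[0], h[1]),
        )
        best_ident, best_id, best_sp = hits[0]
        rival = next(
            (h for h in hits[1:]
             if h[2] != best_sp and best_ident - h[0] <= ambiguity_window),
            None,
        )
        if best_ident < threshold:
            call = "novel-species-level"
        elif rival is not None:
            call = "ambiguous"
        else:
            call = "assigned-to-species"
        out.append(TaxAssignment(
            otu_id=cl.otu_id,
            best_ref=best_id,
            species=best_sp,
            identity_pct=best_ident,
            call=call,
            threshold_used=threshold,
        ))
    return out


# ---------------------------------------------------------------------------
# pipeline orchestration

@dataclass
class ProfileResult:
    otus: list[OtuCluster]
    abundance: pd.DataFrame
    taxonomy: list[TaxAssignment]
    chimeras: list[Unique]
    n_unmapped: int
    stage_counts: dict[str, int]

    def summary(self) -> str:
        lines = ["amplicon profiling summary", "-" * 28]
        for k, v in self.stage_counts.items():
            lines.append(f"{k:>26}: {v}")
        lines.append(f"{'OTUs':>26}: {len(self.otus)}")
        for tax in self.taxonomy:
            lines.append(
                f"  {tax.otu_id}: {tax.call} ({tax.species}, "
                f"{tax.identity_pct:.2f}% vs {tax.best_ref})"
            )
        return "\n".join(lines)


def profile(
    reads: Sequence[SequenceRecord],
    reference: Sequence[SequenceRecord],
    fwd_primer: DegeneratePrimer | None = None,
    marker: str = "tils",
    cluster_threshold: float = DEFAULT_CLUSTER_ID,
    map_threshold: float = DEFAULT_CLUSTER_ID,
    max_expected_errors: float = 1.0,
    min_len: int = 0,
    max_len: int | None = None,
    min_abundance: int = 1,
    thresholds: Mapping[str, float] = PAPER_2023_THRESHOLDS,
) -> ProfileResult:
    """Run the full profiling pipeline on a read set.

    Every input read ends in exactly one bin: dropped by quality/length,
    unanchored, member of a chimeric unique, mapped to an OTU, or
    unmapped.
    """
    n_input = len(reads)
    if reads and reads[0].quality is not None:
        filtered, qstats = quality_filter(
            reads, max_expected_errors, min_len, max_len
        )
    else:
        filtered, qstats = list(reads), {"kept": n_input,
                                         "dropped_quality": 0,
                                         "dropped_length": 0}
    if fwd_primer is not None:
        anchored, astats = anchor_on_primer(filtered, fwd_primer)
    else:
        anchored, astats = filtered, {"kept": len(filtered),
                                      "dropped_unanchored": 0}
    uniques = dereplicate(anchored)
    low_ab = [u for u in uniques if u.abundance < min_abundance]
    n_low_ab_reads = sum(u.abundance for u in low_ab)
    low_ab_ids = {rid for u in low_ab for rid in u.read_ids}
    uniques = [u for u in uniques if u.abundance >= min_abundance]
    kept_uniques, chimeras = screen_chimeras(uniques)
    n_chimera_reads = sum(u.abundance for u in chimeras)
    otus = cluster_greedy(kept_uniques, cluster_threshold)
    excluded_ids = {rid for u in chimeras for rid in u.read_ids} | low_ab_ids
    mappable = [r for r in anchored if r.id not in excluded_ids]
    abundance, n_unmapped, _ = map_reads(mappable, otus, map_threshold)
    taxonomy = assign_taxonomy(otus, reference, marker, thresholds)
    stage_counts = {
        "input_reads": n_input,
        "dropped_quality": qstats["dropped_quality"],
        "dropped_length": qstats["dropped_length"],
        "dropped_unanchored": astats["dropped_unanchored"],
        "low_abundance_reads": n_low_ab_reads,
        "chimeric_reads": n_chimera_reads,
        "mapped_reads": int(abundance["member_count"].sum()),
        "unmapped_reads": n_unmapped,
    }
    return ProfileResult(
        otus=otus,
        abundance=abundance,
        taxonomy=taxonomy,
        chimeras=chimeras,
        n_unmapped=n_unmapped,
        stage_counts=stage_counts,
    )
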