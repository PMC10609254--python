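"""Synthetic data: genomes diverged on a known tree, markers, reads.

The generator emulates the statistical structure of a genus-level clade
of sulfur-bacterium genomes:

* a pure-birth (Yule) tree over the taxa, scaled so the root-to-tip
  height equals ``base_divergence`` expected substitutions per site;
* sequences evolved down that tree under the K80 (Kimura 2-parameter)
  model with transition/transversion rate ratio ``kappa`` — no indels,
  so the expected identity between any two taxa is a closed form of
  their tree distance and every downstream estimate has an analytic
  truth value;
* marker genes embedded at fixed loci, each with its own rate
  multiplier (a fast clock-like marker resolves species, a slow one
  reproduces the ">98% identity everywhere" failure mode of typical
  housekeeping genes);
* the tilS-like marker carries invariant footprints matching the
  packaged TilS primers, so in-silico PCR yields a 619 bp product in
  every genome;
* amplicon read sets drawn from those products with per-base
  substitution errors (Phred values consistent with the error rate) and
  optional two-parent chimeras spliced at a uniform breakpoint.

Everything is driven by one integer seed; outputs are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy

from .markers import TILS_F, TILS_R, revcomp
from .seqio import SequenceRecord

_BASES = np.array(list("ACGT"))
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV1 = np.array([1, 0, 1, 0])
_TV2 = np.array([3, 2, 3, 2])

#: concrete realisations of the degenerate primer sites planted in the
#: tilS-like marker (Y -> C, M -> A)
FWD_SITE = TILS_F.sequence.replace("Y", "C")
REV_SITE = revcomp(TILS_R.sequence.replace("M", "A").replace("Y", "C"))
AMPLICON_LEN = 619


def k80_probabilities(d: float | np.ndarray, kappa: float):
    """(p_transition, p_each_transversion) after distance ``d``.

    ``d`` is the expected number of substitutions per site; ``kappa``
    the transition/transversion *rate* ratio alpha/beta.
    """
    d = np.asarray(d, dtype=float)
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e4b = np.exp(-4.0 * bt)
    e2ab = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b  # each of the two transversion targets
    return p_ts, p_tv


def expected_diff_proportion(d: float, kappa: float = 2.0) -> float:
    """Expected proportion of differing sites between two sequences at
    total tree distance ``d`` (multiple hits corrected)."""
    p_ts, p_tv = k80_probabilities(d, kappa)
    return float(p_ts + 2.0 * p_tv)


def simulate_tree(
    n_taxa: int, seed: int, birth_rate: float = 1.0
) -> dendropy.Tree:
    """Ultrametric pure-birth tree, root-to-tip height normalised to 1."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    t = 0.0
    tips: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        tips.append((child, 0.0))
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        k = int(rng.integers(len(tips)))
        node, born = tips.pop(k)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            tips.append((child, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    for node, born in tips:
        node.edge.length = t_end - born
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        taxon = ns.new_taxon(f"T{i:0{width}d}")
        leaf.taxon = taxon
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_end
    return tree


def _mutate(idx: np.ndarray, d_per_site: np.ndarray, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = k80_probabilities(d_per_site, kappa)
    u = rng.random(idx.shape[0])
    out = idx.copy()
    sel = u < p_ts
    out[sel] = _TRANSITION[idx[sel]]
    sel = (u >= p_ts) & (u < p_ts + p_tv)
    out[sel] = _TV1[idx[sel]]
    sel = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[sel] = _TV2[idx[sel]]
    return out


def _evolve(root_idx: np.ndarray, tree: dendropy.Tree, kappa: float,
            site_rates: np.ndarray, rng: np.random.Generator
            ) -> dict[str, np.ndarray]:
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_idx}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = seqs[id(node.parent_node)]
        d = (node.edge.length or 0.0) * site_rates
        child = _mutate(parent, d, kappa, rng)
        seqs[id(node)] = child
        if node.is_leaf() and node.taxon is not None:
            out[node.taxon.label] = child
    return out


def evolve_sequences(
    root_seq: str | SequenceRecord,
    tree: dendropy.Tree,
    kappa: float = 2.0,
    rate_multiplier: float = 1.0,
    seed: int = 0,
) -> dict[str, SequenceRecord]:
    """Evolve one sequence down a tree under K80 (no indels)."""
    seq = root_seq.residues if isinstance(root_seq, SequenceRecord) else root_seq
    if not seq:
        raise ValueError("empty root sequence")
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    idx = lut[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (idx < 0).any():
        raise ValueError("root sequence must be plain ACGT")
    rng = np.random.default_rng(seed)
    rates = np.full(len(seq), float(rate_multiplier))
    leaves = _evolve(idx, tree, kappa, rates, rng)
    return {
        lab: SequenceRecord(id=lab, residues="".join(_BASES[v]))
        for lab, v in leaves.items()
    }


@dataclass(frozen=True)
class MarkerSpec:
    name: str
    length: int
    rate_multiplier: float
    with_primers: bool = False  # plant invariant TilS primer footprints


@dataclass(frozen=True)
class ReadProfile:
    n_reads: int = 2000
    read_len: int = 250
    error_rate: float = 0.005
    #: log-sd of the per-read error-rate spread (lognormal around
    #: ``error_rate``); real runs mix good and bad reads, which is what
    #: makes expected-error filtering selective rather than all-or-none
    error_spread: float = 0.6
    chimera_rate: float = 0.02
    abundance: tuple[float, ...] | None = None  # uniform when None

    def __post_init__(self) -> None:
        if not (0.0 <= self.chimera_rate < 1.0):
            raise ValueError("chimera_rate must be in [0, 1)")


#: study conditions: an 8-taxon genus-level clade, 60 kb genomes,
#: root-to-tip divergence 5% (pairwise divergences span roughly 1-10%),
#: a clock-like tilS-style marker carrying the primer sites, a larger
#: rpoB-style marker, and a slow decoy reproducing the near-uniform
#:-identity failure mode.
DEFAULT_MARKERS = (
    MarkerSpec("tils_like", 1300, 1.0, with_primers=True),
    MarkerSpec("rpob_like", 3500, 0.8),
    MarkerSpec("slow_decoy", 1200, 0.1),
)


@dataclass
class SimParams:
    seed: int = 0
    n_taxa: int = 8
    genome_len: int = 60_000
    base_divergence: float = 0.05
    kappa: float = 2.0
    markers: tuple[MarkerSpec, ...] = DEFAULT_MARKERS
    read_profile: ReadProfile = field(default_factory=ReadProfile)
    #: explicit tree (branch lengths in substitutions/site); when given
    #: it is used as-is and n_taxa/base_divergence are ignored
    tree: dendropy.Tree | None = None

    def __post_init__(self) -> None:
        if any(m.rate_multiplier <= 0 for m in self.markers):
            raise ValueError("rate multipliers must be > 0")


@dataclass
class MarkerTruth:
    spec: MarkerSpec
    start: int  # 0-based half-open locus on every genome
    end: int
    genes: dict[str, SequenceRecord]


@dataclass
class SimTruth:
    tree: dendropy.Tree  # branch lengths in substitutions/site
    pair_distance: pd.DataFrame  # tree distance per taxon pair
    expected_ani: pd.DataFrame  # 100 * (1 - expected diff proportion)
    markers: dict[str, MarkerTruth]
    kappa: float

    def expected_identity(self, a: str, b: str,
                          rate_multiplier: float = 1.0) -> float:
        d = float(self.pair_distance.loc[a, b]) * rate_multiplier
        return 100.0 * (1.0 - expected_diff_proportion(d, self.kappa))


def _tree_distances(tree: dendropy.Tree) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in tree.taxon_namespace:
        for b in tree.taxon_namespace:
            mat.loc[a.label, b.label] = pdm.distance(a, b)
    return mat


def build_genomes(
    params: SimParams,
) -> tuple[dict[str, SequenceRecord], SimTruth]:
    """Simulate a clade of genomes with embedded marker genes.

    Marker loci are identical across taxa (no rearrangement — fragment
    ANI is insensitive to synteny at this scale) and are spaced evenly
    through the genome. Primer footprints in the tilS-like marker never
    mutate, so the packaged primers amplify a 619 bp product from every
    genome.
    """
    rng = np.random.default_rng(params.seed)
    if params.tree is not None:
        tree = params.tree
    else:
        tree = simulate_tree(params.n_taxa, params.seed + 1)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= params.base_divergence

    total_marker = sum(m.length for m in params.markers)
    if total_marker + 1000 > params.genome_len:
        raise ValueError("markers do not fit in genome_len with disjoint loci")

    # lay out marker loci with even spacing
    gap = (params.genome_len - total_marker) // (len(params.markers) + 1)
    loci: list[tuple[MarkerSpec, int, int]] = []
    pos = gap
    for spec in params.markers:
        loci.append((spec, pos, pos + spec.length))
        pos += spec.length + gap

    root_idx = rng.integers(0, 4, size=params.genome_len)
    rates = np.ones(params.genome_len)
    for spec, start, end in loci:
        rates[start:end] = spec.rate_multiplier
        if spec.with_primers:
            lut = np.full(256, -1, dtype=np.int64)
            for i, b in enumerate("ACGT"):
                lut[ord(b)] = i
            amp_start = start + (spec.length - AMPLICON_LEN) // 2
            f_end = amp_start + len(FWD_SITE)
            r_start = amp_start + AMPLICON_LEN - len(REV_SITE)
            root_idx[amp_start:f_end] = lut[
                np.frombuffer(FWD_SITE.encode(), dtype=np.uint8)]
            root_idx[r_start : amp_start + AMPLICON_LEN] = lut[
                np.frombuffer(REV_SITE.encode(), dtype=np.uint8)]
            rates[amp_start:f_end] = 0.0
            rates[r_start : amp_start + AMPLICON_LEN] = 0.0

    leaves = _evolve(root_idx, tree, params.kappa, rates, rng)
    genomes = {
        lab: SequenceRecord(id=lab, residues="".join(_BASES[v]))
        for lab, v in sorted(leaves.items())
    }

    dist = _tree_distances(tree)
    exp_ani = 100.0 * (1.0 - dist.map(
        lambda d: expected_diff_proportion(d, params.kappa)))
    np.fill_diagonal(exp_ani.values, 100.0)

    markers: dict[str, MarkerTruth] = {}
    for spec, start, end in loci:
        genes = {
            lab: SequenceRecord(id=lab, residues=g.residues[start:end])
            for lab, g in genomes.items()
        }
        markers[spec.name] = MarkerTruth(spec, start, end, genes)

    truth = SimTruth(
        tree=tree,
        pair_distance=dist,
        expected_ani=exp_ani,
        markers=markers,
        kappa=params.kappa,
    )
    return genomes, truth


def simulate_reads(
    genomes: Mapping[str, SequenceRecord],
    truth: SimTruth,
    profile: ReadProfile = ReadProfile(),
    seed: int = 0,
) -> list[SequenceRecord]:
    """Draw amplicon reads (with errors and chimeras) from the genomes.

    Reads start at the first base after the forward primer footprint of
    the tilS-like amplicon (forward-anchored reads include the primer;
    see the amplicon pipeline's anchoring stage) — here the primer IS
    included so the pipeline's anchor/trim stage is exercised. Phred
    values are uniform per read and consistent with ``error_rate``.
    Chimeric reads splice the amplicons of two distinct taxa at a
    uniform breakpoint; their description records both parents.
    """
    from .markers import insilico_pcr  # local import avoids cycles

    rng = np.random.default_rng(seed)
    taxa = sorted(genomes)
    amps: dict[str, str] = {}
    for lab in taxa:
        prods = insilico_pcr(TILS_F, TILS_R, genomes[lab])
        if not prods:
            raise ValueError(f"tilS-like marker not amplifiable in {lab}")
        amps[lab] = prods[0].sequence
    if profile.abundance is None:
        weights = np.full(len(taxa), 1.0 / len(taxa))
    else:
        if len(profile.abundance) != len(taxa):
            raise ValueError("abundance length != number of taxa")
        weights = np.asarray(profile.abundance, dtype=float)
        weights = weights / weights.sum()

    reads: list[SequenceRecord] = []
    for i in range(profile.n_reads):
        # per-read error rate; Phred value is derived from it after
        # rounding and the realised errors use the rounded rate, so
        # quality and error process agree exactly
        if profile.error_rate <= 0:
            q, e_read = 40, 0.0
        else:
            e = profile.error_rate * float(
                np.exp(rng.normal(0.0, profile.error_spread)))
            q = int(np.clip(round(-10.0 * np.log10(max(e, 1e-4))), 2, 40))
            e_read = 10.0 ** (-q / 10.0)
        if rng.random() < profile.chimera_rate:
            a, b = rng.choice(len(taxa), size=2, replace=False)
            la, lb = taxa[a], taxa[b]
            L = min(len(amps[la]), len(amps[lb]), profile.read_len)
            # breakpoint inside the sequenced window, with margins wide
            # enough that both segments are substantial after primer
            # trimming — a simulated chimera is an observable two-parent
            # artifact, not a few-base splice
            lo, hi = 60, L - 30
            if hi <= lo:
                lo, hi = L // 3, 2 * L // 3 + 1
            cut = int(rng.integers(lo, hi))
            template = amps[la][:cut] + amps[lb][cut:]
            desc = f"chimera={la}|{lb}|{cut}"
        else:
            k = int(rng.choice(len(taxa), p=weights))
            template = amps[taxa[k]]
            desc = f"taxon={taxa[k]}"
        seq = template[: profile.read_len]
        if e_read > 0:
            lut = np.full(256, 0, dtype=np.int64)
            for j, b2 in enumerate("ACGT"):
                lut[ord(b2)] = j
            idx = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
            err = rng.random(len(idx)) < e_read
            shift = rng.integers(1, 4, size=len(idx))
            idx[err] = (idx[err] + shift[err]) % 4
            seq = "".join(_BASES[idx])
        reads.append(SequenceRecord(
            id=f"read{i + 1}",
            residues=seq,
            description=desc,
            quality=[q] * len(seq),
        ))
    return reads
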