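"""Scoring candidate marker genes against whole-genome evidence.

A good single-gene marker for a genus must (i) track genome-wide ANI
closely enough that gene identity can be extrapolated to ANI, and (ii)
reproduce the reference (whole-genome) tree topology. This module
quantifies both, derives species partitions from ANI at the 95%
species threshold, and scans gene-identity thresholds that separate
within-species from between-species pairs.

Species-delineation thresholds published for the *Thiothrix* markers
are shipped as the ``paper_2023`` constant set (tilS 91.85%, rpoB
95.59%); they are applied as given, not re-derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .pairwise import DistanceMatrix, IdentityMatrix
from .phylo import nj_tree, rf_distance

#: ANI above which two genomes are conspecific
SPECIES_ANI_THRESHOLD = 95.0

#: published species-delineation identity thresholds per marker
PAPER_2023_THRESHOLDS: dict[str, float] = {"tils": 91.85, "rpob": 95.59}


class SpeciesPartition(dict):
    """Mapping genome id -> species cluster id (0-based, deterministic)."""

    @property
    def n_clusters(self) -> int:
        return len(set(self.values()))

    def same_species(self, a: str, b: str) -> bool:
        return self[a] == self[b]


def species_partition(
    ani: IdentityMatrix, threshold: float = SPECIES_ANI_THRESHOLD
) -> SpeciesPartition:
    """Single-linkage components of the graph with edges ANI >= threshold.

    Missing (NaN) cells are treated as below threshold, with a warning.
    Cluster ids are assigned by the smallest member label, so the
    partition is invariant to label order.
    """
    vals = ani.values
    if np.isnan(vals).any():
        warnings.warn("missing ANI cells treated as below threshold",
                      stacklevel=2)
    adj = np.nan_to_num(vals, nan=-np.inf) >= threshold
    _, comp = connected_components(csr_matrix(adj), directed=False)
    # relabel components deterministically by their smallest member label
    first = {}
    for lab, c in sorted(zip(ani.labels, comp)):
        first.setdefault(c, lab)
    order = {c: rank for rank, (lab, c) in enumerate(
        sorted((lab, c) for c, lab in first.items()))}
    return SpeciesPartition(
        (lab, order[c]) for lab, c in zip(ani.labels, comp)
    )


def _pair_frame(gene_ident: IdentityMatrix, ani: IdentityMatrix) -> pd.DataFrame:
    if set(gene_ident.labels) != set(ani.labels):
        raise ValueError("gene and ANI matrices have different label sets")
    rows = []
    labs = sorted(gene_ident.labels)
    for i, a in enumerate(labs):
        for b in labs[i + 1 :]:
            g = gene_ident.get(a, b)
            v = ani.get(a, b)
            rows.append((a, b, g, v, abs(g - v)))
    df = pd.DataFrame(rows, columns=["a", "b", "gene_pct", "ani_pct", "abs_dev"])
    return df


def ani_concordance(
    gene_ident: IdentityMatrix, ani: IdentityMatrix
) -> tuple[float, float, pd.DataFrame]:
    """(mean |gene - ANI|, max |gene - ANI|, per-pair table).

    Deviations are in percentage points over unordered pairs, diagonal
    excluded; pairs with a missing ANI cell are dropped with a warning.
    """
    df = _pair_frame(gene_ident, ani)
    n_missing = int(df["ani_pct"].isna().sum() + df["gene_pct"].isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} pairs with missing cells dropped",
                      stacklevel=2)
        df = df.dropna(subset=["gene_pct", "ani_pct"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no comparable pairs")
    return float(df["abs_dev"].mean()), float(df["abs_dev"].max()), df


@dataclass
class ThresholdScan:
    """Separability of within- vs between-species gene identities."""

    min_within: float
    max_between: float
    margin: float  # min_within - max_between; > 0 iff one threshold separates
    best_threshold: float
    violations: list[tuple[str, str, float, str]]  # (a, b, identity, kind)
    n_within: int
    n_between: int


def threshold_scan(
    gene_ident: IdentityMatrix, partition: SpeciesPartition
) -> ThresholdScan:
    """Scan gene-identity thresholds against a species partition.

    With a positive margin the best threshold is the midpoint of the
    gap and there are no violations; otherwise the threshold minimising
    misclassified pairs is chosen (smallest such threshold, for
    determinism) and the misclassified pairs are listed: between-species
    pairs at or above it (e.g. a marker blind to a species split) and
    within-species pairs below it.
    """
    missing = set(gene_ident.labels) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover labels {sorted(missing)}")
    labs = sorted(gene_ident.labels)
    within, between = [], []
    for i, a in enumerate(labs):
        for b in labs[i + 1 :]:
            v = gene_ident.get(a, b)
            if np.isnan(v):
                continue
            (within if partition.same_species(a, b) else between).append(
                (a, b, v)
            )
    if not between:
        raise ValueError(
            "partition has a single cluster: between-species statistics "
            "undefined"
        )
    if not within:
        raise ValueError("no within-species pairs under this partition")
    min_within = min(v for _, _, v in within)
    max_between = max(v for _, _, v in between)
    margin = min_within - max_between

    if margin > 0:
        best = 0.5 * (min_within + max_between)
        violations: list[tuple[str, str, float, str]] = []
    else:
        idents = sorted({v for _, _, v in within} | {v for _, _, v in between})
        candidates = [idents[0] - 0.5] + [
            0.5 * (x + y) for x, y in zip(idents, idents[1:])
        ] + [idents[-1] + 0.5]
        def miscount(t: float) -> int:
            return sum(1 for *_, v in within if v < t) + sum(
                1 for *_, v in between if v >= t
            )
        best = min(candidates, key=lambda t: (miscount(t), t))
        violations = sorted(
            [(a, b, v, "within-below-threshold")
             for a, b, v in within if v < best]
            + [(a, b, v, "between-above-threshold")
               for a, b, v in between if v >= best]
        )
    return ThresholdScan(
        min_within=min_within,
        max_between=max_between,
        margin=margin,
        best_threshold=best,
        violations=violations,
        n_within=len(within),
        n_between=len(between),
    )


@dataclass
class MarkerEvalReport:
    gene: str
    mean_abs_dev: float
    max_abs_dev: float
    rf_to_reference: int
    min_within: float
    max_between: float
    margin: float
    violations: list[tuple[str, str, float, str]] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def identity_to_distance(ident: IdentityMatrix) -> DistanceMatrix:
    """p-distance matrix (1 - identity/100) for tree building."""
    vals = 1.0 - ident.values / 100.0
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(ident.labels, vals)


def evaluate_markers(
    genes: Mapping[str, IdentityMatrix],
    ani: IdentityMatrix,
    reference_tree: dendropy.Tree,
    species_threshold: float = SPECIES_ANI_THRESHOLD,
) -> list[MarkerEvalReport]:
    """Rank candidate markers by species-separation fidelity.

    For each gene: identity-to-ANI deviation statistics, the RF distance
    of its NJ tree (on p-distances from identity) to the reference tree,
    and the within/between separation under the ANI species partition.
    Ranking: fewest violations, then lowest RF, then lowest mean
    deviation.
    """
    ref_leaves = {lf.taxon.label for lf in reference_tree.leaf_node_iter()
                  if lf.taxon}
    if set(ani.labels) != ref_leaves:
        raise ValueError("ANI labels do not match reference tree leaves")
    partition = species_partition(ani, species_threshold)
    reports = []
    for gene_name, ident in genes.items():
        mean_dev, max_dev, _ = ani_concordance(ident, ani)
        gene_tree = nj_tree(identity_to_distance(ident))
        rf = rf_distance(gene_tree, reference_tree)
        scan = threshold_scan(ident, partition)
        reports.append(MarkerEvalReport(
            gene=gene_name,
            mean_abs_dev=mean_dev,
            max_abs_dev=max_dev,
            rf_to_reference=rf,
            min_within=scan.min_within,
            max_between=scan.max_between,
            margin=scan.margin,
            violations=scan.violations,
        ))
    reports.sort(key=lambda r: (r.n_violations, r.rf_to_reference,
                                r.mean_abs_dev, r.gene))
    return reports


def reports_to_frame(reports: Sequence[MarkerEvalReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": r.gene,
            "mean_abs_dev": round(r.mean_abs_dev, 2),
            "max_abs_dev": round(r.max_abs_dev, 2),
            "rf_to_reference": r.rf_to_reference,
            "min_within": round(r.min_within, 2),
            "max_between": round(r.max_between, 2),
            "margin": round(r.margin, 2),
            "n_violations": r.n_violations,
            "violations": ";".join(
                f"{a}|{b}|{v:.2f}|{kind}" for a, b, v, kind in r.violations
            ),
        }
        for r in reports
    )
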