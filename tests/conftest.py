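import numpy as np
import pytest

from thiomarker.seqio import SequenceRecord, read_newick
from thiomarker.synthetic import SimParams, ReadProfile, build_genomes, simulate_reads


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Plant exactly n_subs substitutions at distinct random positions."""
    arr = list(seq)
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


@pytest.fixture(scope="session")
def clade():
    """An 8-taxon simulated clade with markers; shared read-only."""
    params = SimParams(seed=2024, genome_len=40_000)
    genomes, truth = build_genomes(params)
    return params, genomes, truth


@pytest.fixture(scope="session")
def balanced4():
    """4 species at >= 5% pairwise divergence, with amplicon reads."""
    tree = read_newick("((A:0.03,B:0.03):0.015,(C:0.03,D:0.03):0.015);")
    params = SimParams(seed=77, genome_len=30_000, tree=tree)
    genomes, truth = build_genomes(params)
    reads = simulate_reads(
        genomes, truth, ReadProfile(n_reads=500, chimera_rate=0.0), seed=9
    )
    reference = [
        SequenceRecord(
            id=f"{lab}_tils", residues=g.residues,
            description=f"species=Species_{lab}",
        )
        for lab, g in truth.markers["tils_like"].genes.items()
    ]
    return genomes, truth, reads, reference
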