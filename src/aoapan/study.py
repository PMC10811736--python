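"""The reference synthetic study: a self-contained genome collection and
metagenome emulating a comparative-pangenomics survey of ammonia-oxidizing
archaea, with one focal order-level lineage against a background order.

The analysis drivers and the reproduction script both build their inputs
from here, so every reported number traces to one generating design:

* 12 genomes in two lineages (5 focal "Nitrosomirales-like", 7 background),
  12-family core, a 20-family accessory pool with presence probabilities
  0.15-0.75, 5 focal-specific (enriched) families, and ~3 unique genes per
  genome; genes of 450 bp (150 aa) diverged 10% within families.
* a 200 kb genome pair at 5% nucleotide divergence for ANI and a 12-protein
  proteome pair at 20% amino-acid divergence for AAI;
* planted marker alignments for conserved-block trimming and supermatrix
  assembly (multiple alignment itself is an input to the pipeline, so the
  study plants alignments rather than computing them);
* a 10 000-read community at 30/70 lineage composition with 1% read error.

All sub-seeds derive from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord
from .orthology import ProteinEntry, all_vs_all_hits, cluster_orthogroups, filter_ortho_hits
from .synthetic import (
    AA_ALPHABET,
    PangenomeSpec,
    SyntheticPangenome,
    evolve_sequence,
    random_sequence,
    simulate_pangenome,
)

FOCAL_LINEAGE = "Nitrosomirales-like"
OTHER_LINEAGE = "Nitrosopumilales-like"


def reference_spec(seed: int) -> PangenomeSpec:
    labels = [FOCAL_LINEAGE] * 5 + [OTHER_LINEAGE] * 7
    rng = np.random.default_rng(seed)
    pool = [
        (f"acc{j:04d}", float(p))
        for j, p in enumerate(rng.uniform(0.15, 0.75, size=20), start=1)
    ]
    return PangenomeSpec(
        n_genomes=12,
        core_size=12,
        accessory_pool=pool,
        unique_rate=3.0,
        gene_length=450,
        family_divergence=0.1,
        lineage_labels=labels,
        enriched_families=[(f"enr{j:04d}", FOCAL_LINEAGE) for j in range(1, 6)],
        seed=seed,
    )


def build_reference_collection(seed: int) -> SyntheticPangenome:
    return simulate_pangenome(reference_spec(seed))


def collection_proteins(collection: SyntheticPangenome) -> list[ProteinEntry]:
    return [
        ProteinEntry(p.id, g, p.sequence)
        for g, ps in collection.proteomes.items()
        for p in ps
    ]


def cluster_collection(collection: SyntheticPangenome):
    """All-vs-all 50/50 orthogroup clustering of the collection's proteins."""
    proteins = collection_proteins(collection)
    hits = filter_ortho_hits(all_vs_all_hits(proteins))
    return cluster_orthogroups(hits, proteins), proteins


@dataclass
class DivergedPair:
    """A genome or proteome pair with planted divergence d."""

    d: float
    genome_a: SequenceRecord
    genome_b: SequenceRecord


def diverged_genome_pair(seed: int, d: float = 0.05, length: int = 200_000) -> DivergedPair:
    rng = np.random.default_rng(seed)
    base = random_sequence(length, rng)
    return DivergedPair(
        d=d,
        genome_a=SequenceRecord(id="genomeA", sequence=base),
        genome_b=SequenceRecord(id="genomeB", sequence=evolve_sequence(base, d, rng)),
    )


def diverged_proteome_pair(
    seed: int, d: float = 0.2, n_proteins: int = 12, length: int = 150
) -> tuple[float, list[SequenceRecord], list[SequenceRecord]]:
    rng = np.random.default_rng(seed)
    seqs = [random_sequence(length, rng, AA_ALPHABET) for _ in range(n_proteins)]
    a = [SequenceRecord(id=f"pA|p{i + 1:02d}", sequence=s) for i, s in enumerate(seqs)]
    b = [
        SequenceRecord(
            id=f"pB|p{i + 1:02d}",
            sequence=evolve_sequence(s, d, rng, alphabet=AA_ALPHABET),
        )
        for i, s in enumerate(seqs)
    ]
    return d, a, b


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Independent sub-seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
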