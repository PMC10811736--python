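"""Orthogroup clustering from all-vs-all protein comparison.

Proteins from all genomes are compared all-against-all by optimal local
alignment (with an exact k-mer prefilter to skip pairs that cannot align),
hits are filtered at 50% identity and 50% pairwise coverage — coverage is
enforced on *both* query and subject, a symmetric rule that avoids chaining
fragments — and orthogroups are the connected components of the surviving
similarity graph. Components are deterministic and parameter-free, unlike
inflation-based clustering; proteins with no surviving edge form singleton
orthogroups, so orthogroups always partition the protein set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .align import local_align, shared_kmer_count


@dataclass(frozen=True)
class ProteinEntry:
    """One protein with its gene id (globally unique) and source genome."""

    gene_id: str
    genome_id: str
    sequence: str


@dataclass(frozen=True)
class OrthoHit:
    """A pairwise protein hit with identity and both-sided coverage."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_coverage: float  # aligned span / query length, in [0, 1]
    subject_coverage: float
    score: float


@dataclass
class Orthogroup:
    og_id: str
    members: frozenset[str]
    genomes: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def all_vs_all_hits(
    proteins: list[ProteinEntry], k: int = 4, min_kmer_shared: int = 1
) -> list[OrthoHit]:
    """Align every protein pair sharing >= ``min_kmer_shared`` k-mers.

    One hit per unordered pair (self-hits excluded); identity is identical
    columns over all alignment columns, coverage is the aligned span over
    each sequence's length. Set ``min_kmer_shared=0`` to disable the
    prefilter and align every pair.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    seen: set[str] = set()
    for p in proteins:
        if not p.sequence:
            raise ValueError(f"protein {p.gene_id!r} has an empty sequence")
        if p.gene_id in seen:
            raise ValueError(f"duplicate gene id {p.gene_id!r}")
        seen.add(p.gene_id)

    hits: list[OrthoHit] = []
    for i in range(len(proteins)):
        a = proteins[i]
        for j in range(i + 1, len(proteins)):
            b = proteins[j]
            if min_kmer_shared > 0:
                if shared_kmer_count(a.sequence, b.sequence, k) < min_kmer_shared:
                    continue
            aln = local_align(a.sequence, b.sequence, protein=True)
            if aln is None:
                continue
            hits.append(
                OrthoHit(
                    query_id=a.gene_id,
                    subject_id=b.gene_id,
                    percent_identity=aln.identity_pct,
                    alignment_length=aln.alignment_length,
                    query_coverage=aln.query_coverage(len(a.sequence)),
                    subject_coverage=aln.target_coverage(len(b.sequence)),
                    score=aln.score,
                )
            )
    return hits


def filter_ortho_hits(
    hits: list[OrthoHit], min_identity: float = 50.0, min_coverage: float = 50.0
) -> list[OrthoHit]:
    """Keep hits at >= ``min_identity`` % identity and >= ``min_coverage`` %
    coverage on both query and subject. Thresholds are inclusive."""
    frac = min_coverage / 100.0
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity
        and h.query_coverage >= frac
        and h.subject_coverage >= frac
    ]


def cluster_orthogroups(
    filtered_hits: list[OrthoHit], all_proteins: list[ProteinEntry]
) -> list[Orthogroup]:
    """Connected components of the filtered similarity graph.

    Every protein lands in exactly one orthogroup; edge-less proteins form
    singletons. Orthogroup ids are assigned by the sorted smallest member
    gene id, so the labelling is deterministic.
    """
    by_gene = {p.gene_id: p for p in all_proteins}
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(by_gene)
    for h in filtered_hits:
        if h.query_id not in by_gene or h.subject_id not in by_gene:
            missing = h.query_id if h.query_id not in by_gene else h.subject_id
            raise ValueError(f"hit references unknown protein {missing!r}")
        graph.add_edge(h.query_id, h.subject_id)

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    ogs = []
    for idx, members in enumerate(components):
        ogs.append(
            Orthogroup(
                og_id=f"OG{idx + 1:05d}",
                members=frozenset(members),
                genomes=frozenset(by_gene[m].genome_id for m in members),
            )
        )
    return ogs


def build_presence_matrix(
    orthogroups: list[Orthogroup],
    genome_ids: list[str],
    counts: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Binary OG x genome occupancy matrix with sorted, deterministic axes."""
    genome_ids = sorted(genome_ids)
    known = set(genome_ids)
    matrix = pd.DataFrame(
        0, index=sorted(og.og_id for og in orthogroups), columns=genome_ids, dtype="int8"
    )
    for og in orthogroups:
        for g in og.genomes:
            if g not in known:
                raise ValueError(
                    f"orthogroup {og.og_id} references unknown genome {g!r}"
                )
            matrix.at[og.og_id, g] = 1
    return matrix


def orthogroup_table(
    orthogroups: list[Orthogroup], proteins: list[ProteinEntry]
) -> pd.DataFrame:
    """Long-form membership table (og_id, gene_id, genome_id)."""
    genome_of = {p.gene_id: p.genome_id for p in proteins}
    rows = [
        (og.og_id, gene, genome_of[gene])
        for og in orthogroups
        for gene in sorted(og.members)
    ]
    return pd.DataFrame(rows, columns=["og_id", "gene_id", "genome_id"])
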