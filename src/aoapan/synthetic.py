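"""Synthetic pangenomes, diverged sequences, read communities, and alignments.

Every generator here produces labelled ground truth so that each stage of the
pipeline (orthogroup clustering, rarefaction, ANI/AAI, block selection, read
recruitment) can be tested for recovery without any external data. All
generators are pure functions of their parameters and a seed.

The pangenome model: a set of gene families, each with an ancestral sequence.
Core families occur in every genome; each accessory family ``f`` occurs in a
genome independently with its own probability ``p_f``; each genome addition-
ally carries a Poisson-distributed number of unique genes (fresh random
sequences, so they sit at alphabet-background identity to everything else
and always fall below a 50% clustering threshold). Genome nucleotide
sequence is the concatenation of its genes with short random spacers, so the
genome size used for per-Mbp normalisation is the actual sequence length.

Substitution model for diverged copies: each position is replaced with
probability ``d`` by a uniformly chosen *different* residue, so the expected
identity to the input is exactly ``1 - d`` with no back-substitution algebra
and no indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import LineageMap, SequenceRecord

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator, alphabet: str = NT_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def evolve_sequence(
    seq: str, d: float, seed: int | np.random.Generator, alphabet: str | None = None
) -> str:
    """Mutate each position independently with probability ``d``.

    A mutated position always receives a *different* residue drawn uniformly
    from the rest of the alphabet, so the expected identity between input
    and output is exactly ``1 - d``. No indels are introduced. The alphabet
    is inferred from the sequence when not given (nucleotide if the sequence
    uses only ACGTN).
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"divergence d={d} outside [0, 1]")
    rng = _rng(seed)
    if alphabet is None:
        alphabet = NT_ALPHABET if set(seq) <= set("ACGTN") else AA_ALPHABET
    chars = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(seq)) < d
    if hit.any():
        order = np.sort(np.frombuffer(alphabet.encode(), dtype="S1"))
        pos = np.searchsorted(order, chars[hit])
        # a uniform offset 1..|A|-1 within the sorted alphabet never returns
        # the original residue, so expected identity is exactly 1 - d
        offset = rng.integers(1, len(alphabet), size=int(hit.sum()))
        chars[hit] = order[(pos + offset) % len(alphabet)]
    return chars.tobytes().decode()


@dataclass
class PangenomeSpec:
    """Parameters of a synthetic multi-genome pangenome."""

    n_genomes: int
    core_size: int
    accessory_pool: list[tuple[str, float]] = field(default_factory=list)
    unique_rate: float = 0.0
    gene_length: int = 450
    family_divergence: float = 0.1
    spacer_length: int = 25
    lineage_labels: list[str] | None = None
    enriched_families: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.core_size < 0 or self.unique_rate < 0:
            raise ValueError("counts must be >= 0")
        for fid, p in self.accessory_pool:
            if not 0.0 < p < 1.0:
                raise ValueError(f"accessory family {fid!r}: p={p} outside (0, 1)")
        if self.lineage_labels is not None and len(self.lineage_labels) != self.n_genomes:
            raise ValueError("lineage_labels length must equal n_genomes")

    @property
    def genome_ids(self) -> list[str]:
        return [f"g{i + 1:03d}" for i in range(self.n_genomes)]


@dataclass
class SyntheticTruth:
    """Ground-truth labels for generated objects."""

    gene_to_family: dict[str, str] = field(default_factory=dict)
    gene_to_genome: dict[str, str] = field(default_factory=dict)
    family_presence: pd.DataFrame | None = None
    pairwise_divergence: dict[tuple[str, str], float] = field(default_factory=dict)
    read_sources: dict[str, str] = field(default_factory=dict)
    conserved_blocks: list[tuple[int, int]] = field(default_factory=list)
    enriched_family_ids: list[str] = field(default_factory=list)

    def family_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, fam in self.gene_to_family.items():
            out.setdefault(fam, set()).add(gene)
        return out


def simulate_presence_matrix(spec: PangenomeSpec, seed: int | None = None) -> pd.DataFrame:
    """Sample only the family x genome occupancy pattern of a pangenome.

    Rows: family ids (core, accessory, enriched, per-genome uniques); columns:
    genome ids; cells 0/1. Families that end up in no genome are dropped
    (they are not part of the realised pangenome).
    """
    rng = _rng(spec.seed if seed is None else seed)
    genomes = spec.genome_ids
    rows: dict[str, np.ndarray] = {}
    for i in range(spec.core_size):
        rows[f"core{i + 1:04d}"] = np.ones(spec.n_genomes, dtype="int8")
    for fid, p in spec.accessory_pool:
        draw = (rng.random(spec.n_genomes) < p).astype("int8")
        if draw.any():
            rows[fid] = draw
    if spec.enriched_families:
        if spec.lineage_labels is None:
            raise ValueError("enriched families require lineage_labels")
        labels = np.asarray(spec.lineage_labels)
        for fid, focal in spec.enriched_families:
            rows[fid] = (labels == focal).astype("int8")
    for gi, g in enumerate(genomes):
        n_unique = int(rng.poisson(spec.unique_rate))
        for u in range(n_unique):
            row = np.zeros(spec.n_genomes, dtype="int8")
            row[gi] = 1
            rows[f"uniq_{g}_{u + 1:03d}"] = row
    if not rows:
        raise ValueError("empty pangenome: no core, accessory, or unique families")
    return pd.DataFrame.from_dict(rows, orient="index", columns=genomes).sort_index()


@dataclass
class SyntheticPangenome:
    """A realised synthetic genome collection with its ground truth."""

    genomes: dict[str, SequenceRecord]
    proteomes: dict[str, list[SequenceRecord]]
    truth: SyntheticTruth
    lineage_map: LineageMap


def simulate_pangenome(spec: PangenomeSpec) -> SyntheticPangenome:
    """Generate genome sequences, proteomes, and ground truth for a spec.

    Each family has a nucleotide ancestor (``gene_length`` bp) and an
    amino-acid ancestor (``gene_length // 3`` aa); every member gene is an
    independently diverged copy of its ancestors at ``family_divergence``.
    Unique genes are fresh random sequences. Genome sequence = concatenated
    genes plus random spacers, in a per-genome shuffled order.
    """
    rng = _rng(spec.seed)
    presence = simulate_presence_matrix(spec, seed=rng)
    genomes = spec.genome_ids
    aa_len = max(30, spec.gene_length // 3)

    ancestors_nt: dict[str, str] = {}
    ancestors_aa: dict[str, str] = {}
    for fam in presence.index:
        if fam.startswith("uniq_"):
            continue
        ancestors_nt[fam] = random_sequence(spec.gene_length, rng, NT_ALPHABET)
        ancestors_aa[fam] = random_sequence(aa_len, rng, AA_ALPHABET)

    truth = SyntheticTruth(
        family_presence=presence,
        enriched_family_ids=sorted(fid for fid, _ in spec.enriched_families),
    )
    genome_records: dict[str, SequenceRecord] = {}
    proteomes: dict[str, list[SequenceRecord]] = {}
    lmap = LineageMap()
    labels = spec.lineage_labels or ["all"] * spec.n_genomes

    for gi, g in enumerate(genomes):
        fams = [f for f in presence.index if presence.at[f, g] == 1]
        order = rng.permutation(len(fams))
        nt_parts: list[str] = []
        prots: list[SequenceRecord] = []
        for oi in order:
            fam = fams[oi]
            gene_id = f"{g}|{fam}"
            if fam.startswith("uniq_"):
                nt = random_sequence(spec.gene_length, rng, NT_ALPHABET)
                aa = random_sequence(aa_len, rng, AA_ALPHABET)
            else:
                nt = evolve_sequence(ancestors_nt[fam], spec.family_divergence, rng)
                aa = evolve_sequence(
                    ancestors_aa[fam], spec.family_divergence, rng, alphabet=AA_ALPHABET
                )
            nt_parts.append(nt)
            if spec.spacer_length:
                nt_parts.append(random_sequence(spec.spacer_length, rng, NT_ALPHABET))
            prots.append(SequenceRecord(id=gene_id, sequence=aa, description=fam))
            truth.gene_to_family[gene_id] = fam
            truth.gene_to_genome[gene_id] = g
        seq = "".join(nt_parts)
        genome_records[g] = SequenceRecord(id=g, sequence=seq)
        proteomes[g] = prots
        lmap.add(g, labels[gi], len(seq))

    return SyntheticPangenome(
        genomes=genome_records, proteomes=proteomes, truth=truth, lineage_map=lmap
    )


def simulate_reads(
    genomes: dict[str, SequenceRecord] | list[SequenceRecord],
    composition: dict[str, float] | list[float],
    read_length: int,
    n_reads: int,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Draw reads from genomes according to a source composition.

    Source genome per read is drawn from ``composition`` (must sum to 1
    within 1e-9); start positions are uniform; each base is substituted with
    probability ``error_rate``. Truth records the source genome of every
    read.
    """
    if isinstance(genomes, list):
        genomes = {r.id: r for r in genomes}
    ids = sorted(genomes)
    if isinstance(composition, dict):
        probs = np.array([composition.get(g, 0.0) for g in ids], dtype=float)
    else:
        if len(composition) != len(ids):
            raise ValueError("composition length must match number of genomes")
        probs = np.asarray(composition, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {probs.sum()}, expected 1")
    min_len = min(len(genomes[g]) for g in ids)
    if read_length > min_len:
        raise ValueError(f"read length {read_length} exceeds shortest genome ({min_len})")

    rng = _rng(seed)
    sources = rng.choice(len(ids), size=n_reads, p=probs)
    reads: list[SequenceRecord] = []
    truth = SyntheticTruth()
    for ri, si in enumerate(sources):
        g = ids[si]
        seq = genomes[g].sequence
        start = int(rng.integers(0, len(seq) - read_length + 1))
        read = seq[start : start + read_length]
        if error_rate > 0:
            read = evolve_sequence(read, error_rate, rng, alphabet=NT_ALPHABET)
        read_id = f"read{ri + 1:06d}"
        reads.append(SequenceRecord(id=read_id, sequence=read))
        truth.read_sources[read_id] = g
    return reads, truth


def simulate_marker_alignment(
    n_seqs: int,
    length: int,
    blocks: list[tuple[int, int]],
    gap_rate: float = 0.5,
    seed: int | np.random.Generator = 0,
    alphabet: str = AA_ALPHABET,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Generate an alignment with planted conserved blocks.

    Columns inside the planted blocks (0-based half-open, disjoint) are
    gap-free and unanimous (one residue across all rows). Columns outside
    carry, per cell, a gap with probability ``gap_rate`` and otherwise a
    uniformly random residue, so with ``gap_rate >= 0.5`` outside columns
    fail any majority-based conservation rule and the planted blocks are the
    unique conserved runs.
    """
    blocks = sorted(blocks)
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        if e1 > s2:
            raise ValueError(f"overlapping blocks [{s1},{e1}) and [{s2},{e2})")
    for s, e in blocks:
        if not (0 <= s < e <= length):
            raise ValueError(f"block [{s},{e}) outside alignment of length {length}")

    rng = _rng(seed)
    cols = np.empty((length, n_seqs), dtype="U1")
    in_block = np.zeros(length, dtype=bool)
    for s, e in blocks:
        in_block[s:e] = True
    alpha = list(alphabet)
    for c in range(length):
        if in_block[c]:
            cols[c, :] = rng.choice(alpha)
        else:
            gap = rng.random(n_seqs) < gap_rate
            residues = rng.choice(alpha, size=n_seqs)
            cols[c, :] = np.where(gap, "-", residues)

    rows = ["".join(cols[:, i]) for i in range(n_seqs)]
    records = [
        SequenceRecord(id=f"s{i + 1:03d}", sequence=row) for i, row in enumerate(rows)
    ]
    truth = SyntheticTruth(conserved_blocks=list(blocks))
    return records, truth
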