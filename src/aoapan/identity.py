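"""Pairwise genome identity: fragment-based ANI, reciprocal-best-hit AAI, GC.

ANI follows the fragment dialect of BLAST-based ANI: the query genome is cut
into consecutive 1020 bp fragments, each fragment's best local alignment in
the subject genome is found (k-mer seeded), and fragments aligning at >= 30%
identity over >= 70% of their length are retained. ANI(A->B) is the mean
identity of retained fragments and the reported value is the mean of the two
directions. AAI is the mean identity over reciprocal best hits between two
proteomes, with the cited tool's default thresholds (40% identity, 50%
coverage) applied to candidate pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .align import KmerIndex, local_align
from .io_formats import SequenceRecord


@dataclass
class PairwiseIdentityResult:
    """ANI or AAI between two genomes, with coverage and support."""

    genome_a: str
    genome_b: str
    metric: str  # "ANI" | "AAI"
    value: float  # percent; NaN when support == 0
    value_ab: float
    value_ba: float
    coverage_ab: float
    coverage_ba: float
    support: int  # retained fragments or RBH pairs

    @property
    def defined(self) -> bool:
        return self.support > 0 and not math.isnan(self.value)


def fragment_genome(
    genome: SequenceRecord, fragment_length: int = 1020
) -> list[SequenceRecord]:
    """Cut a genome into consecutive non-overlapping fragments.

    The final shorter remainder is kept; each fragment's description carries
    its 0-based half-open source coordinates, so concatenating the fragments
    reproduces the genome.
    """
    if not genome.sequence:
        raise ValueError("empty genome")
    fragments = []
    for i, start in enumerate(range(0, len(genome.sequence), fragment_length)):
        end = min(start + fragment_length, len(genome.sequence))
        fragments.append(
            SequenceRecord(
                id=f"{genome.id}_frag{i + 1:05d}",
                sequence=genome.sequence[start:end],
                description=f"{start}..{end}",
            )
        )
    return fragments


def _directional_ani(
    query: SequenceRecord,
    index: KmerIndex,
    fragment_length: int,
    min_frag_identity: float,
    min_frag_coverage: float,
) -> tuple[float, float, int]:
    """(mean retained identity, aligned-base coverage of query, n retained)."""
    identities: list[float] = []
    aligned_bases = 0
    for frag in fragment_genome(query, fragment_length):
        aln = index.seeded_local_align(frag.sequence)
        if aln is None:
            continue
        frag_cov = aln.query_coverage(len(frag.sequence))
        if aln.identity_pct >= min_frag_identity and frag_cov >= min_frag_coverage:
            identities.append(aln.identity_pct)
            aligned_bases += aln.q_end - aln.q_start
    if not identities:
        return math.nan, 0.0, 0
    return (
        sum(identities) / len(identities),
        aligned_bases / len(query.sequence),
        len(identities),
    )


def anib(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    fragment_length: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_coverage: float = 0.7,
) -> PairwiseIdentityResult:
    """Fragment-based average nucleotide identity between two genomes.

    When no fragment is retained in either direction the result carries
    support 0 and an undefined (NaN) value rather than raising.
    """
    ani_ab, cov_ab, n_ab = _directional_ani(
        genome_a, KmerIndex(genome_b.sequence), fragment_length,
        min_frag_identity, min_frag_coverage,
    )
    ani_ba, cov_ba, n_ba = _directional_ani(
        genome_b, KmerIndex(genome_a.sequence), fragment_length,
        min_frag_identity, min_frag_coverage,
    )
    support = n_ab + n_ba
    if support == 0:
        value = math.nan
    elif n_ab and n_ba:
        value = (ani_ab + ani_ba) / 2
    else:
        value = ani_ab if n_ab else ani_ba
    return PairwiseIdentityResult(
        genome_a=genome_a.id,
        genome_b=genome_b.id,
        metric="ANI",
        value=value,
        value_ab=ani_ab,
        value_ba=ani_ba,
        coverage_ab=cov_ab,
        coverage_ba=cov_ba,
        support=support,
    )


def aai(
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
    min_identity: float = 40.0,
    min_coverage: float = 0.5,
) -> PairwiseIdentityResult:
    """Reciprocal-best-hit average amino-acid identity between two proteomes.

    Each protein's best-scoring alignment partner is found in the other
    proteome; mutual best pairs passing the identity threshold and the
    coverage threshold on both sequences are RBHs, and AAI is their mean
    identity. Support is the RBH count; zero RBHs gives an undefined value.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    genome_a = proteome_a[0].id.split("|")[0]
    genome_b = proteome_b[0].id.split("|")[0]

    # one alignment per cross pair, reused for both directions
    alignments: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for pa in proteome_a:
        for pb in proteome_b:
            aln = local_align(pa.sequence, pb.sequence, protein=True)
            if aln is None:
                continue
            alignments[(pa.id, pb.id)] = (
                aln.score,
                aln.identity_pct,
                aln.query_coverage(len(pa.sequence)),
                aln.target_coverage(len(pb.sequence)),
            )

    def best_partner(pid: str, direction: int) -> str | None:
        cands = [
            (v[0], key[1 - direction])
            for key, v in alignments.items()
            if key[direction] == pid
        ]
        if not cands:
            return None
        # highest score; ties to the lexicographically smaller partner
        return min(cands, key=lambda c: (-c[0], c[1]))[1]

    best_a = {p.id: best_partner(p.id, 0) for p in proteome_a}
    best_b = {p.id: best_partner(p.id, 1) for p in proteome_b}

    rbh_identities: list[float] = []
    aligned_cov_a: list[float] = []
    aligned_cov_b: list[float] = []
    for pa_id, pb_id in best_a.items():
        if pb_id is None or best_b.get(pb_id) != pa_id:
            continue
        _, ident, cov_a, cov_b = alignments[(pa_id, pb_id)]
        if ident >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
            rbh_identities.append(ident)
            aligned_cov_a.append(cov_a)
            aligned_cov_b.append(cov_b)

    support = len(rbh_identities)
    value = sum(rbh_identities) / support if support else math.nan
    return PairwiseIdentityResult(
        genome_a=genome_a,
        genome_b=genome_b,
        metric="AAI",
        value=value,
        value_ab=value,
        value_ba=value,
        coverage_ab=sum(aligned_cov_a) / support if support else 0.0,
        coverage_ba=sum(aligned_cov_b) / support if support else 0.0,
        support=support,
    )


def gc_content(genome: SequenceRecord | str) -> float:
    """GC percent over unambiguous bases, reported to one decimal."""
    seq = genome if isinstance(genome, str) else genome.sequence
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return round(100.0 * (counts["G"] + counts["C"]) / denom, 1)
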