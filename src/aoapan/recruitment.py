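"""Competitive fragment recruitment, lineage abundance, and identity screens.

Metagenomic reads are recruited against a multi-genome reference database:
hits are filtered (80% identity, 100 bp alignment, E-value 1e-10 for
imported hit tables), each read is assigned to the single best subject
genome, counts are aggregated per lineage, and lineage counts are
normalized by the lineage's average genome size in Mb — the correction that
removes genome-length bias from read counts so relative abundances reflect
cell proportions.

The "100 bp coverage" filter is read as a minimum alignment length in bp
(the natural reading of a read-mapping filter), not fractional coverage.
The internal read mapper reports no E-value (it has no score statistics);
its hits carry evalue 0.0 and the E-value cut-off is only meaningful for
imported tabular hit files. Ties in the per-read ranking are broken
deterministically: bitscore desc, E-value asc, identity desc, then
lexicographic subject id.

Identity screens (e.g. 16S rRNA at 97% or 95%, amoA at 90%) assign a query
the lineage of its best-aligning reference when the alignment identity
reaches the cut-off; primer-mismatch counting uses IUPAC degeneracy (a
target base matches if it is in the primer position's IUPAC set).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import KmerIndex, local_align
from .io_formats import HitRecord, LineageMap, SequenceRecord

IUPAC_NT = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"), "U": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("GC"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC degeneracy support."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def filter_recruitment_hits(
    hits: list[HitRecord],
    min_identity: float = 80.0,
    min_align_len: int = 100,
    max_evalue: float = 1e-10,
) -> list[HitRecord]:
    """Keep hits at >= 80% identity, >= 100 bp alignment, E-value <= 1e-10.

    All thresholds inclusive; the filter is a subset operation and
    idempotent.
    """
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity
        and h.alignment_length >= min_align_len
        and h.evalue <= max_evalue
    ]


def competitive_assign(hits: list[HitRecord]) -> dict[str, str]:
    """Assign each read to the subject of its single best (filtered) hit.

    Ranking: bitscore desc, E-value asc, identity desc, lexicographic
    subject id. Reads absent from ``hits`` are simply unassigned.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _rank_key(h) < _rank_key(cur):
            best[h.query_id] = h
    return {read: h.subject_id for read, h in best.items()}


def _rank_key(h: HitRecord) -> tuple:
    return (-h.bitscore, h.evalue, -h.percent_identity, h.subject_id)


@dataclass
class RecruitmentProfile:
    """Per-genome and per-lineage recruitment with size normalization."""

    genome_counts: dict[str, int]
    lineage_counts: dict[str, int]
    normalized: dict[str, float]  # reads per Mb of average lineage genome
    relative: dict[str, float]  # normalized / sum(normalized)
    n_assigned: int
    n_unassigned: int

    def as_rows(self) -> list[tuple[str, int, float, float]]:
        return [
            (lin, self.lineage_counts[lin], self.normalized[lin], self.relative[lin])
            for lin in sorted(self.lineage_counts)
        ]


def lineage_abundance(
    assignments: dict[str, str],
    lineage_map: LineageMap,
    n_total_reads: int | None = None,
) -> RecruitmentProfile:
    """Aggregate read assignments to lineages and normalize by genome size.

    The normalizing size of a lineage is the mean genome size (Mb) over all
    *database* genomes of that lineage, not only the genomes that recruited
    reads.
    """
    genome_counts: Counter[str] = Counter()
    for read, genome in assignments.items():
        if genome not in lineage_map:
            raise ValueError(f"assigned genome {genome!r} missing from lineage map")
        genome_counts[genome] += 1
    lineage_counts: Counter[str] = Counter()
    for genome, count in genome_counts.items():
        lineage_counts[lineage_map.lineage(genome)] += count
    normalized = {
        lin: count / lineage_map.mean_size_mb(lin)
        for lin, count in lineage_counts.items()
    }
    denom = sum(normalized.values())
    relative = {lin: v / denom for lin, v in normalized.items()} if denom else {}
    n_assigned = len(assignments)
    n_unassigned = (n_total_reads - n_assigned) if n_total_reads is not None else 0
    return RecruitmentProfile(
        genome_counts=dict(genome_counts),
        lineage_counts=dict(lineage_counts),
        normalized=normalized,
        relative=relative,
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
    )


def map_reads_to_genomes(
    reads: list[SequenceRecord],
    genomes: dict[str, SequenceRecord],
    k: int = 16,
    margin: int = 50,
) -> list[HitRecord]:
    """Map reads against reference genomes by seeded local alignment.

    Emits one 12-column-style hit per read per genome where a positive
    local alignment exists in the read's best seed window. Bitscore is the
    raw alignment score and evalue is reported as 0.0 (no E-value model);
    filter such hits on identity and alignment length.
    """
    indexes = {g: KmerIndex(rec.sequence, k=k) for g, rec in genomes.items()}
    hits: list[HitRecord] = []
    for read in reads:
        for g in sorted(genomes):
            aln = indexes[g].seeded_local_align(read.sequence, margin=margin)
            if aln is None:
                continue
            hits.append(
                HitRecord(
                    query_id=read.id,
                    subject_id=g,
                    percent_identity=aln.identity_pct,
                    alignment_length=aln.alignment_length,
                    mismatches=aln.mismatches,
                    gap_opens=aln.gap_columns,
                    q_start=aln.q_start + 1,
                    q_end=aln.q_end,
                    s_start=aln.t_start + 1,
                    s_end=aln.t_end,
                    evalue=0.0,
                    bitscore=aln.score,
                )
            )
    return hits


@dataclass
class ScreenResult:
    """Best-reference screen outcome for one query sequence."""

    query_id: str
    best_reference: str | None
    identity_pct: float
    lineage: str  # assigned lineage or "unassigned"
    threshold: float


def screen_sequences(
    queries: list[SequenceRecord],
    references: list[SequenceRecord],
    ref_lineages: dict[str, str],
    min_identity: float,
) -> list[ScreenResult]:
    """Assign each query the lineage of its best reference at a cut-off.

    Best reference by local alignment score; the lineage is assigned only
    when alignment identity >= ``min_identity`` (inclusive), otherwise the
    query is reported unassigned.
    """
    if not references:
        raise ValueError("empty reference set")
    if not 0.0 < min_identity <= 100.0:
        raise ValueError(f"min_identity {min_identity} outside (0, 100]")
    results = []
    for q in queries:
        best_ref, best_score, best_ident = None, 0.0, 0.0
        for ref in references:
            aln = local_align(q.sequence, ref.sequence, protein=False)
            if aln is None:
                continue
            if aln.score > best_score or (
                aln.score == best_score and best_ref is not None and ref.id < best_ref
            ):
                best_ref, best_score, best_ident = ref.id, aln.score, aln.identity_pct
        assigned = (
            ref_lineages[best_ref]
            if best_ref is not None and best_ident >= min_identity
            else "unassigned"
        )
        results.append(
            ScreenResult(
                query_id=q.id,
                best_reference=best_ref,
                identity_pct=best_ident,
                lineage=assigned,
                threshold=min_identity,
            )
        )
    return results


def count_primer_mismatches(primer: str, window: str) -> int:
    """Mismatches of a degenerate primer against an equal-length window.

    A position matches when the target base is in the primer position's
    IUPAC set. Reverse primers should be reverse-complemented (see
    :func:`reverse_complement`) before comparison.
    """
    primer = primer.upper()
    window = window.upper()
    if len(window) < len(primer):
        raise ValueError(
            f"window ({len(window)} nt) shorter than primer ({len(primer)} nt)"
        )
    if len(window) != len(primer):
        raise ValueError("window must equal primer length; use best_primer_window")
    mismatches = 0
    for p, t in zip(primer, window):
        if t not in IUPAC_NT.get(p, set()):
            mismatches += 1
    return mismatches


def best_primer_window(primer: str, target: str) -> tuple[int, int]:
    """(offset, mismatches) of the best-matching window over all offsets."""
    if len(target) < len(primer):
        raise ValueError("target shorter than primer")
    best = None
    for offset in range(len(target) - len(primer) + 1):
        mm = count_primer_mismatches(primer, target[offset : offset + len(primer)])
        if best is None or mm < best[1]:
            best = (offset, mm)
    return best
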