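"""Pairwise local alignment and exact-k-mer seeding.

All sequence comparison in the pipeline funnels through :func:`local_align`
(Smith-Waterman with affine gaps, via scikit-bio's ``pair_align``). Identity
is reported over *all* alignment columns including internal gap columns;
terminal overhangs outside the local alignment are excluded — the common
local-alignment identity convention.

For genome-scale searches (1 kb fragments or short reads against whole
genomes), aligning against the full target is wasteful; :class:`KmerIndex`
locates a candidate target window by exact k-mer seeding (diagonal voting,
the BLAST-style seed step) and the optimal local alignment is then computed
inside that window. Queries sharing no k-mer with the target produce no hit.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from skbio.alignment import pair_align

# blastn-like nucleotide scoring; BLOSUM62 with standard gap costs for protein
NT_SCORING = dict(sub_score=(2.0, -3.0), gap_cost=(5.0, 2.0))
AA_SCORING = dict(sub_score="BLOSUM62", gap_cost=(11.0, 1.0))


@dataclass
class LocalAlignment:
    """An optimal local alignment between two sequences."""

    score: float
    identity_pct: float
    alignment_length: int
    matches: int
    mismatches: int
    gap_columns: int
    q_start: int  # 0-based half-open span on the query
    q_end: int
    t_start: int  # and on the target
    t_end: int
    aligned_query: str
    aligned_target: str

    def query_coverage(self, query_length: int) -> float:
        return (self.q_end - self.q_start) / query_length

    def target_coverage(self, target_length: int) -> float:
        return (self.t_end - self.t_start) / target_length


def local_align(query: str, target: str, protein: bool = False) -> LocalAlignment | None:
    """Optimal Smith-Waterman local alignment; ``None`` if no positive score."""
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    scoring = AA_SCORING if protein else NT_SCORING
    res = pair_align(query, target, mode="local", max_paths=1, **scoring)
    if res.score <= 0 or not res.paths:
        return None
    path = res.paths[0]
    aligned_q, aligned_t = path.to_aligned((query, target))
    (q_start, q_end), (t_start, t_end) = path.ranges
    matches = mismatches = gaps = 0
    for a, b in zip(aligned_q, aligned_t):
        if a == "-" or b == "-":
            gaps += 1
        elif a == b:
            matches += 1
        else:
            mismatches += 1
    length = len(aligned_q)
    return LocalAlignment(
        score=float(res.score),
        identity_pct=100.0 * matches / length,
        alignment_length=length,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
        q_start=int(q_start),
        q_end=int(q_end),
        t_start=int(t_start),
        t_end=int(t_end),
        aligned_query=aligned_q,
        aligned_target=aligned_t,
    )


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmer_count(a: str, b: str, k: int) -> int:
    """Number of distinct k-mers occurring in both sequences."""
    if len(a) < k or len(b) < k:
        return 0
    return len(kmer_set(a, k) & kmer_set(b, k))


class KmerIndex:
    """Exact k-mer index over a target sequence for seeded window lookup."""

    def __init__(self, target: str, k: int = 16):
        self.target = target
        self.k = k
        self.positions: dict[str, list[int]] = defaultdict(list)
        for i in range(len(target) - k + 1):
            self.positions[target[i : i + k]].append(i)

    def best_window(self, query: str, margin: int = 64) -> tuple[int, int] | None:
        """Target window around the best-supported seed diagonal.

        Diagonals (target position minus query position) are binned at
        ``margin`` resolution and the bin with the most seed votes wins;
        returns ``None`` when query and target share no k-mer.
        """
        votes: Counter[int] = Counter()
        k = self.k
        for qpos in range(len(query) - k + 1):
            for tpos in self.positions.get(query[qpos : qpos + k], ()):
                votes[(tpos - qpos) // margin] += 1
        if not votes:
            return None
        best_bin = max(votes, key=lambda b: (votes[b], -b))
        diag_lo = best_bin * margin
        lo = max(0, diag_lo - margin)
        hi = min(len(self.target), diag_lo + len(query) + 2 * margin)
        return lo, hi

    def seeded_local_align(
        self, query: str, margin: int = 64
    ) -> LocalAlignment | None:
        """Local alignment of the query inside its best seed window.

        Target coordinates in the result are rebased to the full target.
        """
        window = self.best_window(query, margin=margin)
        if window is None:
            return None
        lo, hi = window
        aln = local_align(query, self.target[lo:hi], protein=False)
        if aln is None:
            return None
        aln.t_start += lo
        aln.t_end += lo
        return aln
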