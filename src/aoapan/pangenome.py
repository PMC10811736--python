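"""Core/pan-genome rarefaction, Heaps'-law openness, and lineage enrichment.

Definitions: for a subset of genomes, the *pan-genome* is the set of
orthogroups present in at least one selected genome and the *core genome*
is the set shared by all of them. For each subset size m out of n genomes
there are n!/[m!(n-m)!] combinations; all are enumerated when that count is
within the cap (default 5000) and otherwise the cap's worth of distinct
combinations is sampled uniformly without replacement.

Pan-genome growth is fitted with Heaps' law, P(N) = kappa * N**gamma, and
the decay of new genes per added genome with n_new(N) = kappa' * N**-alpha;
alpha <= 1 is the classical criterion for an open pan-genome. A second
openness statistic, the average number of new unique orthogroups per Mbp of
genome added, is computed by sequential genome addition averaged over random
addition orders.

The closed-form expectations

    E[pan(m)]  = sum_g  1 - C(n - k_g, m) / C(n, m)
    E[core(m)] = sum_g  C(k_g, m) / C(n, m)

(with k_g the number of genomes carrying orthogroup g) are evaluated in
exact rational arithmetic and serve as the independent oracle for the
sampling procedure.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_formats import LineageMap


def count_combinations(n: int, m: int) -> int:
    """Exact C(n, m) as an arbitrary-precision integer."""
    if m < 0 or n < 0:
        raise ValueError("n and m must be non-negative")
    if m > n:
        raise ValueError(f"m={m} exceeds n={n}")
    return math.comb(n, m)


def sample_combinations(
    n: int, m: int, cap: int = 5000, seed: int | np.random.Generator = 0
) -> tuple[list[tuple[int, ...]], bool]:
    """All C(n, m) index sets if within ``cap``, else ``cap`` distinct ones.

    Returns ``(combinations, exhaustive)``. Sampling is uniform without
    replacement over combinations and deterministic under the seed.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if not 0 < m <= n:
        raise ValueError(f"need 0 < m <= n, got m={m}, n={n}")
    total = math.comb(n, m)
    if total <= cap:
        return list(itertools.combinations(range(n), m)), True
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < cap:
        combo = tuple(sorted(rng.choice(n, size=m, replace=False).tolist()))
        chosen.add(combo)
    return sorted(chosen), False


@dataclass
class PangenomeCurve:
    """Rarefaction means/sds per subset size m (1..n)."""

    table: pd.DataFrame  # columns: m, pan_mean, pan_sd, core_mean, core_sd,
    #          n_combos, exhaustive
    n_genomes: int
    n_ogs: int
    cap: int
    seed: int


def pangenome_curve(
    matrix: pd.DataFrame, cap: int = 5000, seed: int = 0
) -> PangenomeCurve:
    """Rarefy pan and core sizes over sampled genome combinations.

    ``matrix`` is the binary OG x genome occupancy matrix. Standard
    deviations use the sampled population (denominator N).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty presence/absence matrix")
    occ = matrix.to_numpy(dtype=bool)
    n = occ.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(1, n + 1):
        combos, exhaustive = sample_combinations(n, m, cap=cap, seed=rng)
        idx = np.asarray(combos)  # (n_combos, m)
        sub = occ[:, idx]  # (ogs, n_combos, m)
        pans = sub.any(axis=2).sum(axis=0)
        cores = sub.all(axis=2).sum(axis=0)
        rows.append(
            (
                m,
                pans.mean(),
                pans.std(),
                cores.mean(),
                cores.std(),
                len(combos),
                exhaustive,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["m", "pan_mean", "pan_sd", "core_mean", "core_sd", "n_combos", "exhaustive"],
    )
    return PangenomeCurve(
        table=table, n_genomes=n, n_ogs=occ.shape[0], cap=cap, seed=seed
    )


def expected_pan_core_exact(matrix: pd.DataFrame, m: int) -> tuple[Fraction, Fraction]:
    """Exact rational E[pan(m)], E[core(m)] under uniform combination sampling."""
    occ = matrix.to_numpy(dtype=bool)
    n = occ.shape[1]
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
    total = math.comb(n, m)
    k_counts = occ.sum(axis=1)
    e_pan = Fraction(0)
    e_core = Fraction(0)
    for k in k_counts:
        k = int(k)
        e_pan += 1 - Fraction(math.comb(n - k, m), total)
        e_core += Fraction(math.comb(k, m), total)
    return e_pan, e_core


@dataclass
class HeapsFit:
    """Power-law fits of pan-genome growth and new-gene decay."""

    kappa_pan: float
    gamma: float
    kappa_new: float
    alpha: float
    rss_pan: float
    rss_new: float

    @property
    def open_flag(self) -> bool:
        """Open pan-genome by the classical criterion alpha <= 1."""
        return self.alpha <= 1.0


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least squares on log y vs log x; returns (coef, exponent, rss)."""
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    rss = float(((ly - (slope * lx + intercept)) ** 2).sum())
    return float(np.exp(intercept)), float(slope), rss


def fit_heaps(curve: PangenomeCurve) -> HeapsFit:
    """Fit P(N) = kappa N^gamma and n_new(N) = kappa' N^-alpha.

    Both fits are ordinary least squares on log-log scale (deterministic and
    closed-form, the standard treatment for pan-genome openness). New-gene
    means are first differences of the pan means; non-positive differences
    are excluded with a warning, and fewer than 3 usable points is an error.
    """
    t = curve.table
    ns = t["m"].to_numpy(dtype=float)
    pans = t["pan_mean"].to_numpy(dtype=float)
    if len(ns) < 3:
        raise ValueError("need at least 3 points to fit Heaps' law")
    if (pans <= 0).any():
        raise ValueError("pan means must be positive")
    kappa_pan, gamma, rss_pan = _loglog_fit(ns, pans)

    new_n = ns[1:]
    new_vals = np.diff(pans)
    keep = new_vals > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {(~keep).sum()} non-positive new-gene points from the decay fit"
        )
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable new-gene points")
    kappa_new, slope, rss_new = _loglog_fit(new_n[keep], new_vals[keep])
    return HeapsFit(
        kappa_pan=kappa_pan,
        gamma=gamma,
        kappa_new=kappa_new,
        alpha=-slope,
        rss_pan=rss_pan,
        rss_new=rss_new,
    )


@dataclass
class OpennessResult:
    """New unique orthogroups per Mbp of genome, by sequential addition."""

    new_genes_per_mbp: float
    per_order: list[float]
    n_orders: int
    seed: int


def openness_new_genes_per_mbp(
    matrix: pd.DataFrame,
    genome_sizes_bp: dict[str, float],
    n_orders: int = 100,
    seed: int = 0,
) -> OpennessResult:
    """Average new orthogroups per Mbp per added genome over random orders.

    For each addition order, every genome after the first contributes
    (orthogroups not seen in earlier genomes) / (its size in Mbp); the
    statistic averages these contributions over positions and orders. The
    first genome of an order contributes no term (the statistic measures
    what each *new* genome adds). When n! <= ``n_orders`` all permutations
    are enumerated instead of sampled.
    """
    genomes = list(matrix.columns)
    missing = [g for g in genomes if g not in genome_sizes_bp]
    if missing:
        raise ValueError(f"missing genome sizes for {missing}")
    occ = matrix.to_numpy(dtype=bool)
    n = len(genomes)
    sizes_mb = np.array([genome_sizes_bp[g] / 1e6 for g in genomes])

    if math.factorial(n) <= n_orders:
        orders = [list(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n).tolist() for _ in range(n_orders)]

    per_order: list[float] = []
    contributions: list[float] = []
    for order in orders:
        seen = np.zeros(occ.shape[0], dtype=bool)
        seen |= occ[:, order[0]]
        order_contribs = []
        for gi in order[1:]:
            new = int((occ[:, gi] & ~seen).sum())
            order_contribs.append(new / sizes_mb[gi])
            seen |= occ[:, gi]
        per_order.append(float(np.mean(order_contribs)) if order_contribs else 0.0)
        contributions.extend(order_contribs)
    value = float(np.mean(contributions)) if contributions else 0.0
    return OpennessResult(
        new_genes_per_mbp=value, per_order=per_order, n_orders=len(orders), seed=seed
    )


def detect_enriched_ogs(
    matrix: pd.DataFrame,
    lineage_map: LineageMap,
    focal: str,
    min_focal_prev: float = 0.8,
    max_other_prev: float = 0.1,
) -> list[str]:
    """Orthogroups enriched in the focal lineage but absent or scarce elsewhere.

    Prevalence >= ``min_focal_prev`` among focal genomes and <=
    ``max_other_prev`` among all other genomes; both thresholds inclusive.
    """
    focal_genomes = [g for g in matrix.columns if g in lineage_map and lineage_map.lineage(g) == focal]
    if not focal_genomes:
        raise ValueError(f"no genomes in matrix belong to lineage {focal!r}")
    other_genomes = [g for g in matrix.columns if g not in focal_genomes]
    focal_prev = matrix[focal_genomes].mean(axis=1)
    if other_genomes:
        other_prev = matrix[other_genomes].mean(axis=1)
    else:
        other_prev = pd.Series(0.0, index=matrix.index)
    mask = (focal_prev >= min_focal_prev) & (other_prev <= max_other_prev)
    return sorted(matrix.index[mask])


def filter_genomes_by_completeness(
    genome_ids: list[str],
    completeness: dict[str, float],
    min_completeness: float = 50.0,
) -> list[str]:
    """Keep genomes with completeness strictly over the threshold.

    Completeness estimates (percent) come from an external tool; a genome
    at exactly the threshold is excluded.
    """
    missing = [g for g in genome_ids if g not in completeness]
    if missing:
        raise ValueError(f"missing completeness values for {missing}")
    kept = [g for g in genome_ids if completeness[g] > min_completeness]
    if not kept:
        warnings.warn("no genomes survive the completeness filter")
    return kept
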