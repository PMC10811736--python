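# Methods

`aoapan` implements the comparative-pangenomics and biogeography
computations used to characterise order-level lineages of ammonia-oxidizing
archaea (AOA): orthogroup clustering from all-vs-all protein comparison,
core/pan-genome rarefaction with Heaps'-law openness, fragment-based ANI and
reciprocal-best-hit AAI, conserved-block supermatrix construction, and
competitive metagenomic fragment recruitment with genome-size-normalized
lineage abundances. A synthetic-data generator with full ground truth stands
in for genome and metagenome downloads, so every stage is testable for
*recovery* of planted signal.

## Alignment engine

All sequence comparison funnels through one Smith-Waterman local aligner
(scikit-bio `pair_align`, affine gaps): BLOSUM62 with gap open/extend 11/1
for protein, match/mismatch 2/−3 with gaps 5/2 for nucleotide. Identity is
identical columns over **all** alignment columns, including internal gap
columns; terminal overhangs outside the local alignment are excluded. The
aligner has no E-value model; E-value thresholds apply only to imported
tabular hit files, and internally identity + length thresholds carry the
filtering. For genome-scale searches (1 kb fragments or 150 bp reads against
whole genomes), an exact 16-mer index locates the best-supported seed
diagonal (BLAST-style diagonal voting, bin width = the alignment margin) and
the optimal local alignment is computed inside that window. A query sharing
no k-mer with the target yields no hit, which is what makes unrelated random
genomes come out with recruitment/ANI support 0 rather than spurious
low-identity matches. The test suite checks the engine against an
independent full-DP Gotoh oracle scored with Biopython's BLOSUM62.

## Orthogroups

Proteins are compared all-against-all (a 4-mer prefilter skips pairs
sharing no 4-mer; it is disabled in oracle tests), hits are kept at ≥50%
identity and ≥50% coverage, and orthogroups are the connected components of
the surviving graph. Three deliberate choices:

* **Coverage is enforced on both query and subject.** A one-sided rule lets
  short fragments chain unrelated full-length proteins; the symmetric rule
  is the conservative reading of "pairwise coverage".
* **Single-linkage components, not Markov clustering.** Components are
  deterministic, parameter-free, and equal to a trivial transitive-closure
  oracle, which makes the clustering testable exactly. Production orthology
  tools default to MCL; on data with planted families separated from
  background identity the two coincide, but on real continuous similarity
  structure components merge more aggressively. Counts such as "17 691 OGs"
  from real 134-genome collections are therefore engine-dependent and are
  not targets of this package.
* Orthogroup ids are assigned by sorted smallest member id, so runs are
  byte-reproducible.

## Rarefaction and openness

For m of n genomes, pan = orthogroups present in ≥1 selected genome, core =
orthogroups present in all selected. All C(n, m) combinations are
enumerated when C(n, m) ≤ 5000 (the cap is per m); otherwise 5000 distinct
combinations are sampled uniformly without replacement, which keeps the
exhaustive and sampled regimes consistent at the cap boundary. Per-m
standard deviations use the sampled population (denominator N). The exact
expectations

    E[pan(m)]  = Σ_g (1 − C(n−k_g, m)/C(n, m))
    E[core(m)] = Σ_g  C(k_g, m)/C(n, m)

are evaluated in rational arithmetic (`fractions.Fraction`) and serve as the
oracle: exhaustive curves must match them to 1e−12.

Heaps' law P(N) = κN^γ and the new-gene decay n_new(N) = κ′N^−α are fitted
by ordinary least squares on log-log scale — deterministic and closed-form,
the standard treatment for pan-genome openness; α ≤ 1 is declared "open".
Non-positive new-gene means (possible in sampled curves) are excluded with
a warning; fewer than 3 usable points is an error.

The per-Mbp openness statistic adds genomes in random order; each genome
after the first contributes (unseen orthogroups)/(its size in Mbp), and the
statistic averages contributions over positions and orders (100 orders by
default; all n! orders when that is fewer). The first genome contributes no
term: the statistic measures what each *new* genome adds.

Lineage-enriched orthogroups are those with prevalence ≥0.8 among focal
genomes and ≤0.1 among all others (inclusive). The 0.8/0.1 pair is this
package's quantification of "enriched … but absent or scarce"; both are
exposed as parameters. The completeness filter ("over 50%") is strict:
exactly 50% is excluded. Completeness estimation itself is out of scope —
values are supplied externally.

## ANI and AAI

ANI follows the fragment dialect of BLAST-based ANI: 1020 bp consecutive
fragments, best seeded local alignment per fragment, retention at ≥30%
identity over ≥70% of the fragment, ANI(A→B) = mean retained identity,
reported value = mean of the two directions (both exposed). Coverage is
retained aligned bases over the query length. Zero retained fragments gives
support 0 and an undefined (NaN) value, not an exception — at large
evolutionary distance the retention criteria, not the aligner, decide
whether ANI is meaningful, which is why printed ranges extending down to
~68% from real genome collections are not reproduction targets.

AAI is reciprocal best hits: best-scoring partner per protein in each
direction, mutual pairs passing ≥40% identity and ≥50% coverage on both
sequences are RBHs, AAI = their mean identity. Thresholds follow the cited
AAI tool's defaults and are configurable.

GC content is 100·(G+C)/(A+C+G+T) with ambiguous bases excluded from both
numerator and denominator, rounded to one decimal.

## Supermatrix

Marker extraction takes, per genome per marker reference, the single
best-scoring local alignment passing ≥30% identity and ≥50% coverage *of
the reference*; ties break to the longer protein, then the smaller gene id.
Any marker reference set is accepted (the classic archaeal set has 70
markers; the bundled study uses its planted core families).

Conserved-block selection classifies each column by the count of its most
frequent residue: any gap ⇒ nonconserved ("no gaps" policy); count < IS
(default ⌊n/2⌋+1) ⇒ nonconserved; ≥ FS (default ⌈0.85n⌉) ⇒ highly
conserved; otherwise conserved. Runs of more than CP (8) contiguous
nonconserved columns are rejected; segments between rejected runs are
trimmed inward to highly-conserved flanks; blocks shorter than BL (10) are
dropped. This is a faithful-in-spirit re-implementation of the published
trimming scheme with its defaults — fully specified here rather than
bit-compatible with the original binary, whose edge trimming has
undocumented corner cases. Fewer than 4 sequences is an error (the
thresholds degenerate).

Concatenation joins kept columns in sorted marker order; genomes absent
from a marker are gap-filled across its partition, and genomes missing more
than half of all columns (configurable) are dropped with a warning. The
partition table is 1-based inclusive and must tile 1..L exactly — the
writer enforces it. Multiple sequence alignment and maximum-likelihood
inference are inputs/downstream tools, not part of this package.

## Recruitment and screens

Imported 12-column hit tables are filtered at ≥80% identity, ≥100 bp
alignment length, and E-value ≤1e−10 (all inclusive). "100 bp coverage" is
read as minimum alignment length in bp — the natural reading of a
read-mapping filter — not fractional coverage, and is configurable. Each
read goes to the subject of its single best hit (bitscore desc, E-value
asc, identity desc, then lexicographic subject id — deterministic ties, for
reproducibility). Lineage counts are normalized by the lineage's average
genome size in Mb over **all database genomes** of that lineage (not only
genomes that recruited reads), and relative abundance is normalized over
the normalized values — this cancels genome-length bias, so relative
abundances estimate cell composition. The bundled mapper
(`map_reads_to_genomes`) emits hits with evalue 0.0, since the internal
aligner has no E-value model.

Identity screens assign a query its best reference's lineage when alignment
identity meets the cut-off (97/95/90% in the standard 16S/amoA usage);
primer mismatch counting treats a target base as matching when it is in the
primer position's IUPAC set, with reverse primers reverse-complemented
first; a best-window search over all offsets is provided.

## Synthetic data: what it emulates, what it does not

The generator emulates: multi-genome pangenomes with a specified core size,
accessory presence probabilities, planted focal-specific families and
Poisson unique genes; diverged sequence pairs with expected identity exactly
1−d (a mutated position always receives a *different* residue, so no
back-substitution algebra; no indels); read sets from a known lineage
composition with per-base error; and alignments with planted gap-free
unanimous blocks in half-gapped noise. Genome sequence is the concatenation
of genes with short random spacers, so the sizes used for per-Mbp
normalization are actual sequence lengths. Unique genes are fresh random
sequences, guaranteeing they sit at alphabet-background identity and fall
below the 50% clustering threshold — planted-truth separability by
construction.

It does **not** emulate: indels, codon structure, GC skew, rearrangements,
paralogy within genomes, contamination/fragmentation of MAGs, or continuous
similarity gradients between families. Passing recovery tests therefore
shows the pipeline is correct *given* its filters and thresholds, not that
those thresholds are optimal on real AOA data.

## Problem sizes and numerics

The bundled study and tests run at desk scale, chosen so the full pipeline
exercises every code path in minutes: a 12-genome collection (~300
proteins, 450 bp genes at 10% within-family divergence), 200 kb genome
pairs for ANI, 10 000-read communities, 8 planted marker alignments, and
the Heaps-recovery experiment at n = 30 genomes × 20 replicate matrices
(occupancy-only simulation — sequences add nothing to that experiment).
Per-Mbp openness values from ~10 kb synthetic genomes are accordingly ~100×
larger than values from real ~1–3 Mb genomes; the statistic scales inversely
with genome size and only cross-lineage comparisons at matched scale are
meaningful. All randomness flows through `numpy.random.default_rng` seeds;
every generator is a pure function of (parameters, seed). Exact quantities
(combination counts, expectations) use integer/rational arithmetic;
power-law fits are closed-form least squares; float comparisons in tests use
explicit tolerances (1e−12 for exhaustive-vs-exact, binomial 3σ bounds for
stochastic recovery).

## Known limitations

* Single-linkage orthogroups differ from MCL-based tools on real data (see
  above); no paralog/ortholog distinction within orthogroups.
* The seeded aligner can miss a homologous window if divergence destroys
  every shared 16-mer (negligible below d ≈ 0.3 for 1 kb fragments, but a
  real limit for short or highly diverged queries).
* The block trimmer is not bit-compatible with the original trimming
  binary.
* Screens are nucleotide-level; protein-space recruitment (as with
  DIAMOND-style mappers) is supported only through imported hit tables.
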