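# aoapan

Comparative pangenomics and biogeography toolkit for ammonia-oxidizing
archaea (AOA) — and for any multi-genome collection with lineage structure.

Characterising a new order-level prokaryotic lineage from genomes and
metagenomes rests on a small set of quantitative computations: clustering
proteins into orthogroups, rarefying the core and pan-genome, measuring
pan-genome openness, computing pairwise genome identity (ANI/AAI), building
a concatenated marker supermatrix for phylogenomics, and estimating lineage
abundances by competitive read recruitment. `aoapan` implements that whole
chain as a tested library, together with a synthetic-data generator with
full ground truth, so each stage can be verified for *recovery* of planted
signal without downloading genome collections.

## What it computes

* **Orthogroups** — all-vs-all Smith-Waterman protein comparison, hits kept
  at ≥50% identity and ≥50% coverage on both sequences, orthogroups = the
  connected components of the surviving similarity graph; binary
  presence/absence matrix over genomes.
* **Core/pan rarefaction** — for m of n genomes there are n!/[m!(n−m)!]
  combinations; all are enumerated when ≤5000, else 5000 distinct ones are
  sampled. Pan(m) = orthogroups in ≥1 selected genome, core(m) = shared by
  all. The exact expectations E[pan(m)] = Σ_g (1 − C(n−k_g,m)/C(n,m)) and
  E[core(m)] = Σ_g C(k_g,m)/C(n,m) are evaluated rationally as an oracle.
* **Openness** — Heaps' law P(N) = κN^γ and new-gene decay
  n_new(N) = κ′N^−α (α ≤ 1 ⇒ open pan-genome), plus the average number of
  new unique genes per Mbp of genome with sequential genome addition.
* **ANI / AAI / GC** — fragment-based ANI (1020 bp fragments, 30%/70%
  retention, two-direction mean), reciprocal-best-hit AAI (40%/50%
  thresholds), GC content over unambiguous bases.
* **Supermatrix** — best-hit marker extraction, conserved-block trimming
  (IS/FS/CP/BL column classification, "no gaps" policy), partitioned
  concatenation with gap-fill for missing markers.
* **Recruitment & screens** — hit filtering at 80% identity / 100 bp /
  E ≤ 1e−10, per-read competitive assignment, lineage counts normalized by
  average lineage genome size (Mb), relative abundances; 16S/amoA-style
  identity screens (97/95/90% cut-offs) and IUPAC-aware primer-mismatch
  counting.

## Worked example

The `analysis/` drivers run a complete study on a bundled synthetic
collection (12 genomes in two lineages, planted core/accessory/enriched
families, known divergences). Run them in order from the repository root:

```bash
python analysis/01_simulate_collection.py
python analysis/02_cluster_orthogroups.py
python analysis/03_rarefy_pangenome.py
python analysis/04_genome_identity.py
python analysis/05_build_supermatrix.py
python analysis/06_recruit_reads.py
```

Outputs land under `results/`. Representative console output:

```
289 proteins, 6146 raw hits, 1082 pass 50/50
64 orthogroups (33 multi-member, 31 singletons)
core genome: 12 orthogroups shared by all 12 genomes

pan-genome 64 OGs, core 12 OGs
Heaps fit: gamma=0.387, alpha=0.597 (open pan-genome)
new unique genes per Mbp per added genome: 311.9
5 OGs enriched in Nitrosomirales-like: ['OG00022', ..., 'OG00026']

d=0.05: ANI  94.95% (expected  95.0%), coverage 0.999, 394 fragments
d=0.20: ANI  80.17% (expected  80.0%), coverage 0.995, 392 fragments
AAI at d=0.2: 79.64% over 12 reciprocal best hits

10000 hits, 10000 pass filters, 10000/10000 reads assigned (100.0% to their true source)
  Nitrosomirales-like     2921 reads  146050.0 per Mb  relative 0.292
  other-AOA               7079 reads  353950.0 per Mb  relative 0.708
```

Reading the numbers: all 64 planted gene families are recovered as
orthogroups and the 12-family planted core is exact; the fitted new-gene
decay α ≈ 0.6 ≤ 1 marks the collection's pan-genome open; ANI recovers each
planted nucleotide divergence d to within 0.2 of 100(1−d); the five planted
focal-specific families are the five enriched orthogroups with no false
positives; and the 30/70 read community is recovered to within binomial
sampling error (0.292 vs 0.30). The per-Mbp openness value is large only
because synthetic genomes are ~10 kb — the statistic scales inversely with
genome size (see `docs/methods.md`).

## Layout

```
src/aoapan/        library: io_formats, synthetic, align, orthology,
                   pangenome, identity, supermatrix, recruitment, study
analysis/          numbered drivers for the bundled study
scripts/           acceptance.py (reproduction script)
tests/             pytest suite incl. end-to-end recovery tests
docs/methods.md    models, parameters, design choices, limitations
```
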