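#!/usr/bin/env python
"""Cluster the collection's proteins into orthogroups at the 50/50 rule.

Reads the per-genome protein FASTA written by 01_simulate_collection.py,
runs all-vs-all local alignment, filters hits at 50% identity and 50%
both-sided coverage, takes connected components, and writes the orthogroup
membership table and the presence/absence matrix under results/pangenome/.
"""

from pathlib import Path

from aoapan.io_formats import read_fasta, read_lineage_map, write_presence_matrix
from aoapan.orthology import (
    ProteinEntry,
    all_vs_all_hits,
    build_presence_matrix,
    cluster_orthogroups,
    filter_ortho_hits,
    orthogroup_table,
)

COLLECTION = Path("results/collection")
OUT = Path("results/pangenome")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lineages = read_lineage_map(COLLECTION / "lineages.tsv")
    proteins = [
        ProteinEntry(rec.id, genome, rec.sequence)
        for genome in sorted(lineages.entries)
        for rec in read_fasta(COLLECTION / f"{genome}.faa")
    ]
    hits = all_vs_all_hits(proteins)
    kept = filter_ortho_hits(hits)
    ogs = cluster_orthogroups(kept, proteins)
    matrix = build_presence_matrix(ogs, sorted(lineages.entries))

    orthogroup_table(ogs, proteins).to_csv(OUT / "orthogroups.tsv", sep="\t", index=False)
    write_presence_matrix(matrix, OUT / "presence_matrix.tsv")

    multi = sum(1 for og in ogs if len(og) > 1)
    core = int((matrix.sum(axis=1) == matrix.shape[1]).sum())
    print(f"{len(proteins)} proteins, {len(hits)} raw hits, {len(kept)} pass 50/50")
    print(f"{len(ogs)} orthogroups ({multi} multi-member, {len(ogs) - multi} singletons)")
    print(f"core genome: {core} orthogroups shared by all {matrix.shape[1]} genomes")


if __name__ == "__main__":
    main()
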