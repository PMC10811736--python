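#!/usr/bin/env python
"""Rarefy the pan/core genome, fit Heaps' law, and detect enriched OGs.

From the presence matrix of 02_cluster_orthogroups.py: samples up to 5000
genome combinations per subset size, fits the pan-genome power law
P(N) = kappa N^gamma and the new-gene decay n_new(N) = kappa' N^-alpha,
computes the average number of new unique genes per Mbp of genome added,
and lists orthogroups enriched in the focal lineage. Writes the curve,
fit JSON, and enriched-OG list under results/pangenome/.
"""

import json
from pathlib import Path

from aoapan.io_formats import read_lineage_map, read_presence_matrix
from aoapan.pangenome import (
    detect_enriched_ogs,
    fit_heaps,
    openness_new_genes_per_mbp,
    pangenome_curve,
)
from aoapan.study import FOCAL_LINEAGE

SEED = 21
OUT = Path("results/pangenome")


def main() -> None:
    matrix = read_presence_matrix(OUT / "presence_matrix.tsv")
    lineages = read_lineage_map(Path("results/collection") / "lineages.tsv")

    curve = pangenome_curve(matrix, cap=5000, seed=SEED)
    curve.table.to_csv(OUT / "rarefaction_curve.tsv", sep="\t", index=False)
    fit = fit_heaps(curve)

    sizes = {g: lineages.size_bp(g) for g in matrix.columns}
    openness = openness_new_genes_per_mbp(matrix, sizes, n_orders=100, seed=SEED)

    enriched = detect_enriched_ogs(matrix, lineages, FOCAL_LINEAGE)
    (OUT / "enriched_ogs.tsv").write_text("".join(f"{og}\n" for og in enriched))
    (OUT / "heaps_fit.json").write_text(
        json.dumps(
            {
                "kappa_pan": fit.kappa_pan,
                "gamma": fit.gamma,
                "kappa_new": fit.kappa_new,
                "alpha": fit.alpha,
                "open_pangenome": fit.open_flag,
                "new_genes_per_mbp": openness.new_genes_per_mbp,
            },
            indent=2,
        )
        + "\n"
    )

    final = curve.table.iloc[-1]
    print(f"pan-genome {final['pan_mean']:.0f} OGs, core {final['core_mean']:.0f} OGs")
    print(f"Heaps fit: gamma={fit.gamma:.3f}, alpha={fit.alpha:.3f} "
          f"({'open' if fit.open_flag else 'closed'} pan-genome)")
    print(f"new unique genes per Mbp per added genome: {openness.new_genes_per_mbp:.1f}")
    print(f"{len(enriched)} OGs enriched in {FOCAL_LINEAGE}: {enriched}")


if __name__ == "__main__":
    main()
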