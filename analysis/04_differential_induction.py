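"""Call iron-regulated genes per genotype and cluster them.

Applies the method-of-moments NB Wald test (-Fe vs +Fe) within each
genotype with BH FDR at padj < 0.05, takes the union of up-regulated
genes, z-scores their condition means and clusters them; the FIT/PYE
set labels serve as the annotation for the over-representation test of
each cluster.
"""

from pathlib import Path

import pandas as pd

from irondelta import (
    call_iron_regulated,
    condition_means,
    hierarchical_cluster,
    nb_wald_test,
    overrepresentation,
    zscore_rows,
)
from irondelta.io import read_counts, read_gene_sets

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts = read_counts(OUT / "counts.tsv", OUT / "samples.tsv")
    sets = read_gene_sets(OUT / "genesets.tsv")

    up: dict[str, list[str]] = {}
    for genotype in ("wildtype", "clf"):
        rec = nb_wald_test(counts, genotype)
        rec.to_csv(OUT / f"de_{genotype}.tsv", sep="\t", index=False)
        up[genotype] = call_iron_regulated(rec, threshold=0.05, direction="up")
        print(f"{genotype}: {len(up[genotype])} genes up-regulated under -Fe (padj < 0.05)")

    union = sorted(set(up["wildtype"]) | set(up["clf"]))
    print(f"union of iron-induced genes across genotypes: {len(union)}")

    z = zscore_rows(condition_means(counts, union))
    res = hierarchical_cluster(z, k=3)
    res.z_matrix.rename_axis("gene_id").to_csv(OUT / "z_matrix.tsv", sep="\t")
    res.cut_assignments.rename_axis("gene_id").to_csv(OUT / "clusters.tsv", sep="\t")
    (OUT / "gene_order.txt").write_text("\n".join(res.gene_order) + "\n")

    annotation = pd.DataFrame(
        [(g, name) for name, genes in sets.items() for g in genes],
        columns=["gene_id", "term"],
    )
    for cl, members in res.cut_assignments.groupby(res.cut_assignments):
        enr = overrepresentation(list(members.index), annotation, union)
        top = enr.sort_values("p_value").iloc[0]
        print(
            f"cluster {cl} ({len(members)} genes): most enriched label "
            f"{top['term']!r} (count {top['count']}, padj {top['padj']:.2e})"
        )


if __name__ == "__main__":
    main()
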