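"""Simulate the study-design count matrix.

Generates the default synthetic scenario — 45 FIT-dependent genes whose
-Fe/+Fe inductions cycle the published (wildtype, clf) pairs, 45
PYE-dependent genes with near-equal inductions in both genotypes, and
150 background genes — for 2 genotypes x 2 iron conditions x 3
replicates, and writes the counts, sample metadata and gene-set files
under results/.
"""

from pathlib import Path

from irondelta import default_scenario, gene_sets_from_specs, simulate_counts
from irondelta.io import write_counts, write_gene_sets

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    specs, design = default_scenario(45, 45, 150, seed=SEED)
    counts = simulate_counts(specs, design)
    write_counts(counts, OUT / "counts.tsv", OUT / "samples.tsv")
    write_gene_sets(gene_sets_from_specs(specs), OUT / "genesets.tsv")
    print(
        f"simulated {len(specs)} genes x {design.n_samples} samples "
        f"(seed {SEED}); mean count {counts.counts.mean():.1f}"
    )
    print(f"wrote counts.tsv, samples.tsv, genesets.tsv under {OUT}")


if __name__ == "__main__":
    main()
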