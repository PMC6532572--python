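"""Plain-text readers and writers for counts, metadata and gene sets.

Counts TSV: first column ``gene_id``, second ``length_bp``, remaining
columns one per sample. Metadata TSV: ``sample_id``, ``genotype``,
``condition``, ``replicate``. Gene sets come as a two-column TSV
(``set``, ``gene_id``) or GMT (set name, description, then genes).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import CountMatrix


def write_counts(counts: CountMatrix, counts_path, meta_path) -> None:
    counts.to_frame().to_csv(counts_path, sep="\t", index=False)
    counts.samples.to_csv(meta_path, sep="\t", index=False)


def read_counts(counts_path, meta_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t")
    meta = pd.read_csv(meta_path, sep="\t")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "length_bp")]
    if set(sample_cols) != set(meta["sample_id"]):
        raise ValueError("counts columns and metadata sample_ids disagree")
    ordered = meta["sample_id"].tolist()
    return CountMatrix(
        genes=df["gene_id"].tolist(),
        lengths_bp=df["length_bp"].to_numpy(),
        samples=meta,
        counts=df[ordered].to_numpy(),
    )


def read_gene_sets(path) -> dict[str, list[str]]:
    """Load named gene sets from two-column TSV or GMT (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets: dict[str, list[str]] = {}
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = parts[2:]
        return sets
    df = pd.read_csv(path, sep="\t")
    if not {"set", "gene_id"}.issubset(df.columns):
        raise ValueError("gene-set TSV needs columns 'set' and 'gene_id'")
    return {name: grp["gene_id"].tolist() for name, grp in df.groupby("set", sort=False)}


def write_gene_sets(sets: dict[str, list[str]], path) -> None:
    rows = [(name, g) for name, genes in sets.items() for g in genes]
    pd.DataFrame(rows, columns=["set", "gene_id"]).to_csv(path, sep="\t", index=False)
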