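"""Test whether FIT-dependent genes are disproportionately more induced
in clf.

Runs the label-permutation randomization test (10,000 permutations) on
the proportion of FIT-set genes above the y = x diagonal, against the
PYE set, plus the one-sided Mann-Whitney comparison of the two sets'
induction differences; writes the result JSON.
"""

import json
from pathlib import Path

import pandas as pd

from irondelta import randomization_test
from irondelta.io import read_gene_sets

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    fc = pd.read_csv(OUT / "fold_changes.tsv", sep="\t")
    sets = read_gene_sets(OUT / "genesets.tsv")
    deltas = fc.set_index("gene_id")["delta"]
    res = randomization_test(
        deltas, sets["FIT"], sets["PYE"], n_perm=10000, seed=SEED, alternative="greater"
    )
    (OUT / "asymmetry.json").write_text(json.dumps(res.to_dict(), indent=2) + "\n")
    print(
        f"FIT set: {res.p_obs_focal:.1%} of genes above the diagonal vs "
        f"{res.p_obs_comparator:.1%} of the PYE set (difference "
        f"{res.diff_obs:+.3f})"
    )
    print(
        f"one-sided randomization p = {res.p_randomization:.2e} "
        f"({res.n_perm} permutations, add-one rule)"
    )
    print(f"Mann-Whitney U = {res.mw_u:.0f}, one-sided p = {res.mw_p:.2e}")
    print(f"wrote asymmetry.json under {OUT}")


if __name__ == "__main__":
    main()
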