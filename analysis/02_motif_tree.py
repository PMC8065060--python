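#!/usr/bin/env python
"""Cluster the observed cis motifs into a phylogenetic-style tree.

Computes pairwise Levenshtein distances between the nine-residue motifs seen
in the cohort, agglomerates them under the ward.D2 criterion and writes the
tree as Newick, plus the k-cluster cut for a chosen k.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dqmotif.motifs import attach_motifs
from dqmotif.pipeline import load_cohort, motif_tree
from dqmotif.registry import load_default_registry

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.tsv")
    ap.add_argument("--k", type=int, default=7)
    args = ap.parse_args()

    registry = load_default_registry()
    cohort = attach_motifs(load_cohort(args.cohort), registry)
    newick, tree = motif_tree(cohort)
    (RESULTS / "motif_tree.nwk").write_text(newick + "\n")
    cut = tree.cut(args.k)
    pd.Series(cut, name="cluster").rename_axis("motif").to_csv(
        RESULTS / "motif_clusters.tsv", sep="\t")

    print(f"{len(tree.labels)} unique cis motifs clustered; "
          f"cut at k={args.k} gives cluster sizes "
          f"{sorted(pd.Series(cut).value_counts().tolist(), reverse=True)}")
    print(f"wrote {RESULTS/'motif_tree.nwk'} and {RESULTS/'motif_clusters.tsv'}")


if __name__ == "__main__":
    main()
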