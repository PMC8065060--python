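#!/usr/bin/env python
"""Conditional scans: trans motifs and individual residues given cis motifs.

Tests every novel trans motif (assembled across chromosomes) and every
polymorphic residue for disease association before and after adjusting for
the full cis-motif design.  Under the motif model the adjusted signals
should largely vanish: the nine-residue motifs carry the association.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dqmotif.motifs import attach_motifs
from dqmotif.pipeline import load_cohort
from dqmotif.registry import ResiduePanel, load_default_registry
from dqmotif.stats import residue_scan, trans_scan

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.tsv")
    args = ap.parse_args()

    panel = ResiduePanel()
    registry = load_default_registry(panel)
    cohort = attach_motifs(load_cohort(args.cohort), registry, panel)

    trans = trans_scan(cohort, registry, panel)
    trans.to_csv(RESULTS / "trans_motif_scan.tsv", sep="\t", index=False)
    ok = trans[trans["status"] == "ok"]
    print(f"trans motifs: {len(trans)} tested, {len(ok)} with >=5 copies; "
          f"{(ok['p_marginal'] < 0.05).sum()} marginally significant, "
          f"{(ok['p_adjusted'] < 0.05).sum()} still significant after "
          f"cis-motif adjustment")

    residues = residue_scan(cohort, registry, panel=panel)
    residues.to_csv(RESULTS / "residue_scan.tsv", sep="\t", index=False)
    sig_marg = (residues["p_marginal"] < 0.05).sum()
    conf = (residues["status"] == "confounded").sum()
    print(f"residues: {len(residues)} polymorphic positions; "
          f"{sig_marg} marginally significant, {conf} fully captured by "
          f"(confounded with) the motif design")
    print(f"wrote {RESULTS/'trans_motif_scan.tsv'} and {RESULTS/'residue_scan.tsv'}")


if __name__ == "__main__":
    main()
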