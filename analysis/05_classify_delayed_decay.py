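#!/usr/bin/env python
"""Classify degraded and delayed-decay transcripts by the four-way intersection.

Degraded: down-regulated across the control transition, m6A-marked at the
earlier stage, and a final RIP target.  Delayed: additionally fold change
> 1.2 across the same transition in the knockout.
"""

import argparse
import json
import os

import pandas as pd

from phaseclear.de import DEThresholds, call_degs
from phaseclear.decay import classify, ko_fold_change
from phaseclear.quantify import read_expression, read_gene_set


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", default="results/sim")
    parser.add_argument("--fpkm", default="results/fpkm.tsv")
    parser.add_argument("--de", default="results/de_DSG_PS_control.tsv")
    parser.add_argument("--targets", default="results/targets.txt")
    parser.add_argument("--transition", default="DSG:PS")
    parser.add_argument("--out", default="results/decay_DSG_PS.tsv")
    args = parser.parse_args()

    earlier, later = args.transition.split(":")
    expr = read_expression(
        args.fpkm,
        os.path.join(args.dir, "samples.tsv"),
        os.path.join(args.dir, "genes.tsv"),
    )
    de_result = pd.read_csv(args.de, sep="\t", index_col=0)
    _, down_set = call_degs(de_result, DEThresholds())
    m6a_prev = read_gene_set(os.path.join(args.dir, f"m6a_{earlier}.txt"))
    targets = read_gene_set(args.targets)
    fc = ko_fold_change(expr, (earlier, later))

    result = classify(
        expr.gene_ids,
        down_set=down_set,
        m6a_prev=m6a_prev & set(expr.gene_ids),
        targets=targets & set(expr.gene_ids),
        ko_fc=fc,
    )
    print(f"down-regulated ({earlier}->{later}, control): {len(down_set)}")
    print(f"degraded m6A-marked targets: {result.counts['degraded']}")
    print(f"delayed decay in knockout (KO FC>1.2): {result.counts['delayed']}")
    result.table.rename_axis("gene_id").to_csv(args.out, sep="\t")
    with open(args.out + ".json", "w") as fh:
        json.dump(dict(result.counts), fh, indent=2)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
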