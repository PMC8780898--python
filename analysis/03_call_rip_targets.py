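#!/usr/bin/env python
"""Call YTHDF2 RIP targets per replicate and intersect, with correlation QC.

A gene is a replicate target when Input FPKM > 1 and IP/Input FPKM > 1.2;
the final set is the intersection of the replicates.
"""

import argparse
import json
import os

from phaseclear.quantify import read_expression
from phaseclear.rip import RipThresholds, call_targets


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", default="results/sim")
    parser.add_argument("--fpkm", default="results/fpkm.tsv")
    parser.add_argument("--genotype", default="control")
    parser.add_argument("--stage", default="DSG")
    parser.add_argument("--out", default="results/targets.txt")
    args = parser.parse_args()

    expr = read_expression(
        args.fpkm,
        os.path.join(args.dir, "samples.tsv"),
        os.path.join(args.dir, "genes.tsv"),
    )
    call = call_targets(expr, genotype=args.genotype, stage=args.stage,
                        thresholds=RipThresholds())
    for rep, n in sorted(call.replicate_counts.items()):
        print(f"replicate {rep}: {n} targets")
    print(f"final targets (intersection): {len(call.final_targets)}; "
          f"IP replicate Spearman rho = {call.correlation:.3f}")
    with open(args.out, "w") as fh:
        fh.write("\n".join(sorted(call.final_targets)) + "\n")
    with open(args.out + ".json", "w") as fh:
        json.dump({"per_replicate": {str(r): n for r, n in call.replicate_counts.items()},
                   "n_final": len(call.final_targets),
                   "spearman": call.correlation}, fh, indent=2)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
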