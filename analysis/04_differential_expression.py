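#!/usr/bin/env python
"""Stage-transition differential expression in control germ cells.

NB Wald test (median-of-ratios normalization, trend-moderated dispersion)
with BH FDR; DEGs at adjusted p < 0.05 and fold change > 1.5.
"""

import argparse
import os

from phaseclear.de import DEThresholds, de_contrast
from phaseclear.quantify import read_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", default="results/sim")
    parser.add_argument("--transition", default="DSG:PS")
    parser.add_argument("--genotype", default="control")
    parser.add_argument("--out", default="results/de_DSG_PS_control.tsv")
    args = parser.parse_args()

    earlier, later = args.transition.split(":")
    cm = read_dataset(
        os.path.join(args.dir, "counts.tsv"),
        os.path.join(args.dir, "samples.tsv"),
        os.path.join(args.dir, "genes.tsv"),
    )
    result = de_contrast(
        cm, factor="stage", level_a=earlier, level_b=later,
        where={"genotype": args.genotype, "assay": "rna"},
        thresholds=DEThresholds(),
    )
    n_down = int((result["call"] == "down").sum())
    n_up = int((result["call"] == "up").sum())
    print(f"{args.genotype} {earlier}->{later}: {n_down} down-regulated, "
          f"{n_up} up-regulated genes (FDR<0.05, FC>1.5)")
    result.rename_axis("gene_id").to_csv(args.out, sep="\t")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
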