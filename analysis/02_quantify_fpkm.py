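#!/usr/bin/env python
"""Compute per-sample FPKM from the simulated counts and report library depths."""

import argparse
import os

from phaseclear.quantify import compute_fpkm, library_sizes, read_dataset, write_expression


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dir", default="results/sim")
    parser.add_argument("--out", default="results/fpkm.tsv")
    args = parser.parse_args()

    cm = read_dataset(
        os.path.join(args.dir, "counts.tsv"),
        os.path.join(args.dir, "samples.tsv"),
        os.path.join(args.dir, "genes.tsv"),
    )
    sizes = library_sizes(cm)
    print(f"{cm.counts.shape[0]} genes x {cm.counts.shape[1]} libraries; "
          f"library sizes {sizes.min()}-{sizes.max()} "
          f"(median {int(sizes.median())})")
    expr = compute_fpkm(cm)
    write_expression(expr, args.out)
    print(f"wrote FPKM matrix -> {args.out}")


if __name__ == "__main__":
    main()
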