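"""Reading datasets and computing FPKM and group means.

FPKM here is the exact definition applied to gene-level counts:

    FPKM(g, s) = counts(g, s) * 1e9 / (library_size(s) * length_nt(g))

with the library size taken as the column sum of the same matrix.  The unit
conserves mass: for every sample, sum_g FPKM * length_nt = 1e9 exactly.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix
from .errors import ValidationError


def read_gene_set(path) -> frozenset:
    """Newline-delimited gene IDs, no header; blank lines ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def _read_matrix(counts_path) -> pd.DataFrame:
    path = str(counts_path)
    if path.endswith(".mtx"):
        from scipy import io as spio

        mat = spio.mmread(path)
        with open(path + ".rows") as fh:
            rows = [line.strip() for line in fh if line.strip()]
        with open(path + ".cols") as fh:
            cols = [line.strip() for line in fh if line.strip()]
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"matrix {path} has shape {dense.shape}, sidecars name "
                f"{len(rows)} rows and {len(cols)} columns"
            )
        return pd.DataFrame(dense, index=rows, columns=cols)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_dataset(counts_path, samples_path, genes_path) -> CountMatrix:
    """Read and validate a counts + metadata dataset.

    Columns of the count matrix are matched to sample metadata rows by
    ``sample_id`` and rows to the gene table by ``gene_id``; the returned
    matrix is reordered to the metadata order.
    """
    raw = _read_matrix(counts_path)
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    genes = pd.read_csv(genes_path, sep="\t").set_index("gene_id")

    missing_meta = [s for s in raw.columns if s not in samples.index]
    if missing_meta:
        raise ValidationError(
            f"count matrix sample(s) absent from sample table: {missing_meta}"
        )
    missing_cols = [s for s in samples.index if s not in raw.columns]
    if missing_cols:
        raise ValidationError(
            f"sample table sample(s) absent from count matrix: {missing_cols}"
        )
    missing_genes = [g for g in raw.index if g not in genes.index]
    if missing_genes:
        raise ValidationError(
            f"count matrix gene(s) absent from gene table: {missing_genes[:5]}"
        )
    missing_rows = [g for g in genes.index if g not in raw.index]
    if missing_rows:
        raise ValidationError(
            f"gene table gene(s) absent from count matrix: {missing_rows[:5]}"
        )
    values = raw.loc[genes.index, samples.index]
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise ValidationError(f"count matrix {counts_path} contains non-integer cells")
    return CountMatrix(values.astype(np.int64), samples, genes)


def read_expression(fpkm_path, samples_path, genes_path) -> ExpressionMatrix:
    """Read an FPKM matrix written by :func:`write_expression`."""
    raw = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    genes = pd.read_csv(genes_path, sep="\t").set_index("gene_id")
    try:
        values = raw.loc[genes.index, samples.index]
    except KeyError as exc:
        raise ValidationError(f"FPKM matrix {fpkm_path} does not match metadata: {exc}")
    return ExpressionMatrix(values.astype(float), samples, genes)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.fpkm.rename_axis("gene_id").to_csv(path, sep="\t")


def library_sizes(cm: CountMatrix) -> pd.Series:
    """Per-sample total counts (the FPKM denominator)."""
    return cm.counts.sum(axis=0)


def compute_fpkm(cm: CountMatrix, exclude: Iterable[str] = ()) -> ExpressionMatrix:
    """FPKM from gene-level counts; errors on zero-depth samples.

    Samples listed in ``exclude`` are dropped from the result instead of
    raising when their library size is zero.
    """
    exclude = set(exclude)
    keep = [s for s in cm.sample_ids if s not in exclude]
    counts = cm.counts[keep]
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(
            f"sample(s) with zero library size (exclude them explicitly): {zero}"
        )
    length = cm.genes["length_nt"].to_numpy()[:, None].astype(float)
    fpkm = counts.to_numpy() * 1e9 / (totals.to_numpy()[None, :] * length)
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=cm.gene_ids, columns=keep),
        cm.samples.loc[keep],
        cm.genes,
    )


def mean_by_group(
    expr: ExpressionMatrix,
    group_keys: Sequence[str],
    where: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Arithmetic mean FPKM across replicates within each metadata group.

    ``group_keys`` is a subset of {genotype, stage, assay}; ``where`` filters
    samples by equality before grouping (an empty selection is an error that
    names the requested group).
    """
    group_keys = list(group_keys)
    for key in group_keys:
        if key not in expr.samples.columns:
            raise ValidationError(f"unknown grouping key {key!r}")
    sub = expr.select_samples(**(dict(where) if where else {}))
    if sub.fpkm.shape[1] == 0:
        raise ValidationError(f"no samples match selection {dict(where or {})!r}")
    labels = sub.samples[group_keys].astype(str).agg("|".join, axis=1)
    out = {}
    for label in labels.unique():
        cols = labels.index[labels == label]
        out[label] = sub.fpkm[cols].mean(axis=1)
    result = pd.DataFrame(out, index=expr.gene_ids)
    result.columns.name = "|".join(group_keys)
    return result


def group_mean(
    expr: ExpressionMatrix, *, genotype: str, stage: str, assay: str = "rna"
) -> pd.Series:
    """Mean FPKM over the replicates of one (genotype, stage, assay) condition."""
    cols = expr.sample_ids_where(genotype=genotype, stage=stage, assay=assay)
    if not cols:
        raise ValidationError(
            f"no samples for genotype={genotype!r}, stage={stage!r}, assay={assay!r}"
        )
    return expr.fpkm[cols].mean(axis=1)
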