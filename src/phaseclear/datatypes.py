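"""Core in-memory containers: count and FPKM matrices with attached metadata.

Both containers are thin, validated wrappers around pandas objects:

* ``values`` / ``counts`` / ``fpkm``: DataFrame, genes (rows) x samples (columns)
* ``samples``: DataFrame indexed by ``sample_id`` with columns
  ``genotype`` (control | vKO), ``stage``, ``replicate``, ``assay``
  (rna | rip_input | rip_ip)
* ``genes``: DataFrame indexed by ``gene_id`` with column ``length_nt``
  (effective length in nucleotides)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

GENOTYPES = ("control", "vKO")
ASSAYS = ("rna", "rip_input", "rip_ip")
SAMPLE_COLUMNS = ("genotype", "stage", "replicate", "assay")


def _check_sample_table(samples: pd.DataFrame) -> None:
    if samples.index.duplicated().any():
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample_id(s): {dupes}")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table lacks column(s): {missing}")
    bad_gt = sorted(set(samples["genotype"]) - set(GENOTYPES))
    if bad_gt:
        raise ValidationError(f"unknown genotype value(s): {bad_gt}")
    bad_assay = sorted(set(samples["assay"]) - set(ASSAYS))
    if bad_assay:
        raise ValidationError(f"unknown assay value(s): {bad_assay}")
    if (samples["replicate"].astype(int) <= 0).any():
        raise ValidationError("replicate numbers must be positive integers")
    key = samples[list(SAMPLE_COLUMNS)].astype(str).agg("/".join, axis=1)
    if key.duplicated().any():
        raise ValidationError(
            f"duplicate (genotype, stage, replicate, assay) combination(s): "
            f"{sorted(key[key.duplicated()].unique())}"
        )
    # every IP library needs its paired Input from the same lysate
    ip = samples[samples["assay"] == "rip_ip"]
    inp = samples[samples["assay"] == "rip_input"]
    inp_keys = set(map(tuple, inp[["genotype", "stage", "replicate"]].itertuples(index=False)))
    for sid, row in ip.iterrows():
        k = (row["genotype"], row["stage"], row["replicate"])
        if k not in inp_keys:
            raise ValidationError(f"rip_ip sample {sid!r} has no matching rip_input sample")


def _check_gene_table(genes: pd.DataFrame) -> None:
    if genes.index.duplicated().any():
        dupes = genes.index[genes.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene_id(s): {dupes}")
    if "length_nt" not in genes.columns:
        raise ValidationError("gene table lacks column 'length_nt'")
    if (genes["length_nt"] <= 0).any():
        bad = genes.index[genes["length_nt"] <= 0].tolist()
        raise ValidationError(f"non-positive gene length(s) for: {bad[:5]}")


def _check_axes(values: pd.DataFrame, samples: pd.DataFrame, genes: pd.DataFrame) -> None:
    if list(values.index) != list(genes.index):
        raise ValidationError("matrix rows do not match the gene table order")
    if list(values.columns) != list(samples.index):
        raise ValidationError("matrix columns do not match the sample table order")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix; the pipeline's universal input."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        _check_sample_table(self.samples)
        _check_gene_table(self.genes)
        _check_axes(self.counts, self.samples, self.genes)
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("count matrix contains non-integer cells")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    # convenience -----------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def select_samples(self, **criteria) -> "CountMatrix":
        """Sub-matrix of samples matching equality criteria on metadata columns."""
        mask = _criteria_mask(self.samples, criteria)
        sub = self.samples[mask]
        return CountMatrix(self.counts[sub.index], sub, self.genes)

    def sample_ids_where(self, **criteria) -> list:
        return list(self.samples.index[_criteria_mask(self.samples, criteria)])

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.samples[list(SAMPLE_COLUMNS)].equals(other.samples[list(SAMPLE_COLUMNS)])
            and self.genes[["length_nt"]].equals(other.genes[["length_nt"]])
        )


@dataclass
class ExpressionMatrix:
    """FPKM gene x sample matrix sharing the CountMatrix axes."""

    fpkm: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        _check_sample_table(self.samples)
        _check_gene_table(self.genes)
        _check_axes(self.fpkm, self.samples, self.genes)
        if (self.fpkm.to_numpy() < 0).any():
            raise ValidationError("FPKM matrix contains negative values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    def select_samples(self, **criteria) -> "ExpressionMatrix":
        mask = _criteria_mask(self.samples, criteria)
        sub = self.samples[mask]
        return ExpressionMatrix(self.fpkm[sub.index], sub, self.genes)

    def sample_ids_where(self, **criteria) -> list:
        return list(self.samples.index[_criteria_mask(self.samples, criteria)])


def _criteria_mask(samples: pd.DataFrame, criteria: Mapping) -> pd.Series:
    mask = pd.Series(True, index=samples.index)
    for column, wanted in criteria.items():
        if column not in samples.columns:
            raise ValidationError(f"unknown sample metadata column {column!r}")
        if isinstance(wanted, (list, tuple, set, frozenset)):
            mask &= samples[column].isin(list(wanted))
        else:
            mask &= samples[column] == wanted
    return mask
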