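"""Synthetic stage-resolved RNA-seq / RIP-seq generator with planted truth.

The generator draws, per gene, a baseline expression level (log-normal on a
relative scale), a gene class (largest-remainder quotas over the configured
fractions) and planted fold changes across the focal stage transition, then
emits negative-binomial counts for every (genotype, stage, replicate, assay)
library scaled to the expected library size.

Noise model.  Counts are NB via a gamma-Poisson mixture with per-gene mean
``mu`` and dispersion ``alpha`` (Var = mu + alpha * mu^2).  The gamma
(biological) component is drawn once per biological sample; the IP and Input
libraries of a RIP replicate are aliquots of one lysate and therefore share
that draw, so their FPKM ratio carries only counting noise around the planted
enrichment — RNA-seq replicates do not share anything.

Stage structure.  Non-focal stages receive mild per-(gene, stage) log-normal
jitter shared by both genotypes; the two focal stages share a single jitter
draw so that the focal transition carries exactly the planted fold change.
The planted genotype effect applies from the later focal stage onwards
(cleared transcripts stay cleared).
"""

from __future__ import annotations

import os
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .config import GENE_CLASSES, SimConfig
from .datatypes import ASSAYS, GENOTYPES, CountMatrix
from .errors import ConfigError

_DECAYING = ("cleared_target", "persistent_nontarget", "m6a_only", "target_only")
_KO_PERSISTING = ("cleared_target", "persistent_nontarget")
_M6A_CLASSES = ("cleared_target", "m6a_only")
_TARGET_CLASSES = ("cleared_target", "target_only")


def quota_counts(fractions: Mapping[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of ``n`` genes over class fractions."""
    classes = [c for c in GENE_CLASSES if c in fractions]
    exact = np.array([fractions[c] * n for c in classes], dtype=float)
    base = np.floor(exact).astype(int)
    remainder = int(round(n - base.sum()))
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:remainder]] += 1
    return dict(zip(classes, (int(v) for v in base)))


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Planted per-gene ground truth.

    Returns a DataFrame indexed by ``gene_id`` with columns ``gene_class``,
    ``ythdf2_target``, ``wt_fc`` (fold-decrease across the focal transition in
    control), ``ko_fc`` (fold-change, later/earlier, in the knockout),
    ``length_nt``, ``baseline_expr`` and one boolean ``m6a_<stage>`` column
    per stage.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    n = config.n_genes

    quotas = quota_counts(config.class_fractions, n)
    labels = np.concatenate([np.repeat(c, k) for c, k in quotas.items()]) if n else np.array([])
    labels = labels[rng.permutation(n)]

    lo, hi = config.gene_length_range
    length = rng.integers(lo, hi + 1, size=n)
    mu, sigma = config.base_mean_log_params
    baseline = rng.lognormal(mu, sigma, size=n)

    wt_fc = np.ones(n)
    ko_fc = np.ones(n)
    decaying = np.isin(labels, _DECAYING)
    wt_fc[decaying] = rng.uniform(*config.wt_decay_fc, size=int(decaying.sum()))
    persisting = np.isin(labels, _KO_PERSISTING)
    ko_fc[persisting] = rng.uniform(*config.ko_persist_fc, size=int(persisting.sum()))
    ko_decaying = decaying & ~persisting  # decays identically in both genotypes
    ko_fc[ko_decaying] = 1.0 / wt_fc[ko_decaying]

    truth = pd.DataFrame(
        {
            "gene_class": labels,
            "ythdf2_target": np.isin(labels, _TARGET_CLASSES),
            "wt_fc": wt_fc,
            "ko_fc": ko_fc,
            "length_nt": length,
            "baseline_expr": baseline,
        },
        index=pd.Index([f"G{i:06d}" for i in range(n)], name="gene_id"),
    )
    m6a = np.isin(labels, _M6A_CLASSES)
    for stage in config.stages:
        truth[f"m6a_{stage}"] = m6a
    return truth


def m6a_genes(truth: pd.DataFrame, stage: str) -> frozenset:
    """Genes flagged as m6A-modified at ``stage`` in a truth table."""
    column = f"m6a_{stage}"
    if column not in truth.columns:
        raise ConfigError(f"truth table has no m6A status for stage {stage!r}")
    return frozenset(truth.index[truth[column].astype(bool)])


def _expression_program(truth: pd.DataFrame, config: SimConfig) -> Dict[Tuple[str, str], np.ndarray]:
    """Deterministic expected relative expression per (genotype, stage)."""
    rng = np.random.default_rng([config.seed, 12])
    n = len(truth)
    stages = config.stages
    if config.stage_jitter_sigma > 0:
        jitter = rng.lognormal(0.0, config.stage_jitter_sigma, size=(n, len(stages)))
    else:
        jitter = np.ones((n, len(stages)))
    earlier_idx = stages.index(config.focal_transition[0])
    later_idx = stages.index(config.focal_transition[1])
    jitter[:, later_idx] = jitter[:, earlier_idx]

    base = truth["baseline_expr"].to_numpy()
    wt_factor = 1.0 / truth["wt_fc"].to_numpy()
    ko_factor = truth["ko_fc"].to_numpy()
    program: Dict[Tuple[str, str], np.ndarray] = {}
    for genotype in GENOTYPES:
        effect = wt_factor if genotype == "control" else ko_factor
        for si, stage in enumerate(stages):
            expr = base * jitter[:, si]
            if si >= later_idx:
                expr = expr * effect
            program[(genotype, stage)] = expr
    return program


def expected_means(truth: pd.DataFrame, config: SimConfig) -> Dict[Tuple[str, str, str], np.ndarray]:
    """Expected per-gene counts for every (genotype, stage, assay) library.

    This is the deterministic part of :func:`generate_counts` (the NB mean
    before biological and counting noise), exposed for diagnostics and tests.
    """
    program = _expression_program(truth, config)
    length = truth["length_nt"].to_numpy().astype(float)
    is_target = truth["ythdf2_target"].to_numpy()
    enrich = np.where(is_target, config.rip_enrichment, config.rip_enrichment_nontarget)
    means: Dict[Tuple[str, str, str], np.ndarray] = {}
    for (genotype, stage), expr in program.items():
        weight = expr * length
        means[(genotype, stage, "rna")] = weight / weight.sum() * config.library_size
        means[(genotype, stage, "rip_input")] = means[(genotype, stage, "rna")]
        weight_ip = weight * enrich
        means[(genotype, stage, "rip_ip")] = weight_ip / weight_ip.sum() * config.library_size
    return means


def sample_id(genotype: str, stage: str, replicate: int, assay: str) -> str:
    return f"{genotype}_{stage}_r{replicate}_{assay}"


def generate_counts(truth: pd.DataFrame, config: SimConfig) -> CountMatrix:
    """Draw the full count matrix for a truth table.

    Deterministic given ``config.seed``; the sampling order is fixed
    (genotype, stage, replicate; RNA gamma, RIP gamma, then the three assays).
    """
    means = expected_means(truth, config)
    rng = np.random.default_rng([config.seed, 13])
    alpha = config.nb_dispersion
    n = len(truth)

    columns: Dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype in GENOTYPES:
        for stage in config.stages:
            for replicate in range(1, config.n_replicates + 1):
                if alpha > 0:
                    gamma_rna = rng.gamma(1.0 / alpha, alpha, size=n)
                    gamma_rip = rng.gamma(1.0 / alpha, alpha, size=n)
                else:
                    gamma_rna = gamma_rip = np.ones(n)
                noise = {"rna": gamma_rna, "rip_input": gamma_rip, "rip_ip": gamma_rip}
                for assay in ASSAYS:
                    sid = sample_id(genotype, stage, replicate, assay)
                    columns[sid] = rng.poisson(means[(genotype, stage, assay)] * noise[assay])
                    meta_rows.append((sid, genotype, stage, replicate, assay))

    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "genotype", "stage", "replicate", "assay"]
    ).set_index("sample_id")
    counts = pd.DataFrame(columns, index=truth.index)
    genes = truth[["length_nt"]].copy()
    return CountMatrix(counts, samples, genes)


# -- on-disk dataset --------------------------------------------------------

def write_dataset(cm: CountMatrix, truth: pd.DataFrame, directory, *, mtx: bool = False) -> Dict[str, str]:
    """Write a dataset directory: counts, sample/gene tables, truth, m6A lists.

    Layout: ``counts.tsv`` (or ``counts.mtx`` with ``.rows``/``.cols``
    sidecars), ``samples.tsv``, ``genes.tsv``, ``truth.tsv`` and one
    ``m6a_<stage>.txt`` newline-delimited gene list per stage.  Round-trips
    losslessly through :func:`phaseclear.quantify.read_dataset`.
    """
    os.makedirs(directory, exist_ok=True)
    paths: Dict[str, str] = {}

    if mtx:
        from scipy import io as spio
        from scipy import sparse

        counts_path = os.path.join(directory, "counts.mtx")
        spio.mmwrite(counts_path, sparse.csr_matrix(cm.counts.to_numpy()))
        with open(counts_path + ".rows", "w") as fh:
            fh.write("\n".join(cm.counts.index) + "\n")
        with open(counts_path + ".cols", "w") as fh:
            fh.write("\n".join(cm.counts.columns) + "\n")
    else:
        counts_path = os.path.join(directory, "counts.tsv")
        cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    paths["counts"] = counts_path

    paths["samples"] = os.path.join(directory, "samples.tsv")
    cm.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    paths["genes"] = os.path.join(directory, "genes.tsv")
    cm.genes.rename_axis("gene_id").to_csv(paths["genes"], sep="\t")
    paths["truth"] = os.path.join(directory, "truth.tsv")
    truth.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")

    stage_columns = [c for c in truth.columns if c.startswith("m6a_")]
    for column in stage_columns:
        stage = column[len("m6a_"):]
        path = os.path.join(directory, f"m6a_{stage}.txt")
        with open(path, "w") as fh:
            genes = truth.index[truth[column].astype(bool)]
            fh.write("\n".join(genes) + ("\n" if len(genes) else ""))
        paths[column] = path
    return paths


def simulate_dataset(config: SimConfig) -> Tuple[CountMatrix, pd.DataFrame]:
    """Convenience: truth + counts in one call."""
    truth = generate_truth(config)
    return generate_counts(truth, config), truth
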