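"""Configuration of the synthetic stage-resolved RNA-seq / RIP-seq generator.

The generator emulates the study design the downstream rules assume: two
genotypes (``control`` and the germ-cell conditional knockout ``vKO``), an
ordered series of spermatogenic stages, replicated bulk RNA-seq libraries
per (genotype, stage), and paired RIP IP/Input libraries with multiplicative
enrichment of reader-bound transcripts.  Gene classes plant ground truth for
the four-way delayed-decay intersection:

``cleared_target``
    m6A-marked, YTHDF2-bound, decays across the focal stage transition in
    control but shows an up-tendency in the knockout — the class the full
    pipeline is meant to recover.
``persistent_nontarget``
    decays in control and persists in the knockout, but is neither m6A-marked
    nor bound (decoy for criteria 2/3).
``m6a_only`` / ``target_only``
    decay in *both* genotypes and carry only one of the two molecular marks
    (decoys for criteria 3 and 2 respectively, and for criterion 4).
``constitutive``
    no planted change in either genotype.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

import yaml

from .errors import ConfigError

DEFAULT_STAGES: Tuple[str, ...] = ("USG", "DSG", "PS", "RS", "ES")

GENE_CLASSES: Tuple[str, ...] = (
    "cleared_target",
    "persistent_nontarget",
    "m6a_only",
    "target_only",
    "constitutive",
)

DEFAULT_CLASS_FRACTIONS: Mapping[str, float] = {
    "cleared_target": 0.10,
    "persistent_nontarget": 0.10,
    "m6a_only": 0.10,
    "target_only": 0.10,
    "constitutive": 0.60,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Fold-change ranges are expressed as fold *magnitudes* (>= 1):
    ``wt_decay_fc`` is the fold-decrease of a decaying gene across the focal
    transition in control, ``ko_persist_fc`` the fold-increase across the same
    transition in the knockout for persisting classes.
    """

    n_genes: int = 4000
    stages: Tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 2
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    wt_decay_fc: Tuple[float, float] = (2.0, 8.0)
    ko_persist_fc: Tuple[float, float] = (1.25, 2.0)
    rip_enrichment: float = 2.0
    rip_enrichment_nontarget: float = 1.0
    # (mu, sigma) of ln-expression on an arbitrary relative scale; only the
    # shape matters because samples are renormalized to library_size.
    base_mean_log_params: Tuple[float, float] = (math.log(50.0), 1.0)
    nb_dispersion: float = 0.05
    library_size: float = 2_000_000.0
    gene_length_range: Tuple[int, int] = (500, 5000)
    focal_transition: Tuple[str, str] = ("DSG", "PS")
    stage_jitter_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if not self.stages:
            raise ConfigError("stages must be a non-empty ordered sequence")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError(f"stages contains duplicates: {self.stages}")
        if self.n_replicates < 2:
            raise ConfigError(
                f"n_replicates must be >= 2 (replicate intersection is defined "
                f"on two), got {self.n_replicates}"
            )
        fracs = dict(self.class_fractions)
        unknown = set(fracs) - set(GENE_CLASSES)
        if unknown:
            raise ConfigError(f"class_fractions has unknown classes: {sorted(unknown)}")
        if any(v < 0 for v in fracs.values()):
            raise ConfigError(f"class_fractions must be non-negative: {fracs}")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions must sum to 1, got {total!r}")
        for name in ("wt_decay_fc", "ko_persist_fc"):
            lo, hi = getattr(self, name)
            if not (1.0 <= lo <= hi):
                raise ConfigError(f"{name} must satisfy 1 <= lo <= hi, got {(lo, hi)}")
        if self.rip_enrichment <= 0 or self.rip_enrichment_nontarget <= 0:
            raise ConfigError("rip_enrichment factors must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        if self.library_size <= 0:
            raise ConfigError(f"library_size must be positive, got {self.library_size}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError(f"gene_length_range must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.stage_jitter_sigma < 0:
            raise ConfigError("stage_jitter_sigma must be >= 0")
        earlier, later = self.focal_transition
        if earlier not in self.stages or later not in self.stages:
            raise ConfigError(
                f"focal_transition {self.focal_transition} not within stages {self.stages}"
            )
        if self.stages.index(earlier) >= self.stages.index(later):
            raise ConfigError(
                f"focal_transition must be ordered earlier->later, got {self.focal_transition}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def class_counts(self) -> Mapping[str, int]:
        """Realized per-class gene counts under largest-remainder rounding."""
        from .simulate import quota_counts  # local import to avoid a cycle

        return quota_counts(self.class_fractions, self.n_genes)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "stages": list(self.stages),
            "n_replicates": self.n_replicates,
            "class_fractions": dict(self.class_fractions),
            "wt_decay_fc": list(self.wt_decay_fc),
            "ko_persist_fc": list(self.ko_persist_fc),
            "rip_enrichment": self.rip_enrichment,
            "rip_enrichment_nontarget": self.rip_enrichment_nontarget,
            "base_mean_log_params": list(self.base_mean_log_params),
            "nb_dispersion": self.nb_dispersion,
            "library_size": self.library_size,
            "gene_length_range": list(self.gene_length_range),
            "focal_transition": list(self.focal_transition),
            "stage_jitter_sigma": self.stage_jitter_sigma,
            "seed": self.seed,
        }

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance fields."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        for key in ("stages", "wt_decay_fc", "ko_persist_fc", "base_mean_log_params",
                    "gene_length_range", "focal_transition"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)
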