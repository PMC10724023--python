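"""Run configuration shared across pipeline stages.

A single :class:`RunConfig` instance carries every tunable threshold and
numerical setting, plus the master random seed. All stages that write output
embed the seed so a run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: VEP-style consequence terms treated as loss-of-function by default.
DEFAULT_LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "frameshift_variant",
    }
)


@dataclass
class RunConfig:
    """All knobs for a pipeline run.

    Parameters
    ----------
    sift_max:
        Maximum SIFT score for a variant to count as deleterious
        (conventionally 0.05).
    rs_min:
        GERP rejected-substitution score must strictly exceed this for a
        variant to count as deleterious (conventionally 0).
    tpm_expressed_min:
        A gene is "expressed" if its TPM reaches this level in at least
        ``tpm_expressed_min_samples`` samples.
    fixed_min_callrate:
        Minimum fraction of samples with a called genotype for a
        frequency-1 site to be reported as fixed. Set to 0 for a strict
        frequency-only rule.
    burden_mode:
        ``"loci"`` counts carrier loci (total = het + hom); ``"alleles"``
        counts derived alleles (total = (het + 2*hom) / (2*callable)).
    burden_denominator:
        ``"per_sample"`` divides by each sample's callable deleterious loci;
        ``"collection"`` divides by the collection-wide deleterious locus
        count regardless of missingness.
    q_nodes, s_nodes:
        Gauss-Legendre resolution for the allele-frequency and selection
        integrals of the expected site-frequency spectrum.
    n_restarts:
        Seeded random restarts for the DFE maximum-likelihood fit.
    fix_p_b:
        If not None, pin the beneficial-mass parameter at this value rather
        than estimating it.
    contrast_test:
        ``"welch"`` or ``"permutation"`` for the burden contrast.
    n_permutations:
        Resamples for the permutation alternative.
    genome_length_bp:
        Published assembly length used to normalise deleterious
        base-substitution mutation (dBSM) rates; record the assembly chosen.
    """

    # dSNP classification
    sift_max: float = 0.05
    rs_min: float = 0.0
    lof_consequences: frozenset = DEFAULT_LOF_CONSEQUENCES
    fixed_min_callrate: float = 0.8
    # expression
    tpm_expressed_min: float = 1.0
    tpm_expressed_min_samples: int = 1
    expression_weighting: str = "dsnp"  # or "gene"
    # burden
    burden_mode: str = "loci"  # or "alleles"
    burden_denominator: str = "per_sample"  # or "collection"
    # DFE fit
    q_nodes: int = 64
    s_nodes: int = 128
    n_restarts: int = 10
    fix_p_b: float | None = None
    sfs_min_retention: float = 0.9
    # contrasts
    contrast_test: str = "welch"  # or "permutation"
    n_permutations: int = 10_000
    multiple_testing: str | None = None  # "bh" to enable Benjamini-Hochberg
    # bookkeeping
    seed: int = 0
    genome_length_bp: float = 2.2e9

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_max <= 1.0):
            raise ValueError(f"sift_max must be in [0, 1], got {self.sift_max}")
        if not (0.0 <= self.fixed_min_callrate <= 1.0):
            raise ValueError("fixed_min_callrate must be in [0, 1]")
        if self.burden_mode not in ("loci", "alleles"):
            raise ValueError(f"unknown burden_mode {self.burden_mode!r}")
        if self.burden_denominator not in ("per_sample", "collection"):
            raise ValueError(f"unknown burden_denominator {self.burden_denominator!r}")
        if self.contrast_test not in ("welch", "permutation"):
            raise ValueError(f"unknown contrast_test {self.contrast_test!r}")
        if self.genome_length_bp <= 0:
            raise ValueError("genome_length_bp must be positive")
        if self.q_nodes < 2 or self.s_nodes < 2:
            raise ValueError("quadrature needs at least 2 nodes per axis")
        self.lof_consequences = frozenset(self.lof_consequences)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["lof_consequences"] = sorted(self.lof_consequences)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
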