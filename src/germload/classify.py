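"""Deleterious-variant classification, polarization, and fixed-site detection.

A SNP is called deleterious (a dSNP) when both lines of evidence agree:
SIFT score <= 0.05 (amino-acid change predicted intolerant) and GERP
rejected-substitution score strictly positive (site more conserved than
neutrally expected). Missing either score fails the conjunction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_formats import MISSING, GenotypeMatrix, VariantAnnotation

logger = logging.getLogger(__name__)

#: Consequence vocabulary recognised for LOF lookup; anything else warns.
KNOWN_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_region_variant",
        "frameshift_variant",
        "missense_variant",
        "synonymous_variant",
        "intron_variant",
        "intergenic_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "3_prime_UTR_variant",
        "5_prime_UTR_variant",
        "non_coding_transcript_exon_variant",
        "stop_retained_variant",
        "coding_sequence_variant",
    }
)


def classify_dsnp(annotation: VariantAnnotation, cfg: RunConfig) -> bool:
    """True iff SIFT <= cfg.sift_max AND RS > cfg.rs_min; missing scores fail."""
    if annotation.sift_score is None or annotation.rs_score is None:
        return False
    return annotation.sift_score <= cfg.sift_max and annotation.rs_score > cfg.rs_min


def is_lof(annotation: VariantAnnotation, cfg: RunConfig) -> bool:
    """True iff the consequence term is in the configured loss-of-function set."""
    term = annotation.consequence
    if term is None:
        return False
    if term not in KNOWN_CONSEQUENCES and term not in cfg.lof_consequences:
        logger.warning("unknown consequence term %r treated as non-LOF", term)
        return False
    return term in cfg.lof_consequences


def derived_allele_freq(dosages: np.ndarray) -> tuple[float, int]:
    """Derived-allele frequency over non-missing diploid genotypes.

    Returns ``(daf, n_called)`` where daf = sum(dosage) / (2 * n_called).
    Raises on an all-missing site.
    """
    dosages = np.asarray(dosages)
    called = dosages != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("site has no called genotypes")
    daf = float(dosages[called].sum()) / (2.0 * n_called)
    return daf, n_called


@dataclass
class DsnpCallset:
    """Deleterious subset of a collection's variants with per-site DAF.

    ``table`` has one row per dSNP: variant_key, gene_id, sift, rs, daf,
    n_called, lof, fixed. ``n_samples`` is the collection sample count the
    callrate floor is measured against.
    """

    table: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        required = {"variant_key", "gene_id", "sift", "rs", "daf", "n_called", "lof", "fixed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"callset table missing columns: {sorted(missing)}")
        if len(self.table) and not self.table["daf"].between(0, 1).all():
            raise ValueError("daf outside [0, 1]")

    @property
    def variant_keys(self) -> list[str]:
        return list(self.table["variant_key"])

    def __len__(self) -> int:
        return len(self.table)


def build_callset(
    gm: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    cfg: RunConfig,
) -> DsnpCallset:
    """Classify every variant and assemble the deleterious callset.

    Sites where all genotypes are missing are dropped (uncallable); fixed
    flags follow :func:`detect_fixed` semantics.
    """
    if len(annotations) != gm.n_variants:
        raise ValueError("annotation count does not match genotype matrix")
    rows = []
    for j, ann in enumerate(annotations):
        if not classify_dsnp(ann, cfg):
            continue
        col = gm.dosage[:, j]
        if not (col != MISSING).any():
            logger.warning("dSNP %s has no called genotypes; dropped", ann.key)
            continue
        daf, n_called = derived_allele_freq(col)
        rows.append(
            {
                "variant_key": ann.key,
                "gene_id": ann.gene_id,
                "sift": ann.sift_score,
                "rs": ann.rs_score,
                "daf": daf,
                "n_called": n_called,
                "lof": is_lof(ann, cfg),
                "fixed": False,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["variant_key", "gene_id", "sift", "rs", "daf", "n_called", "lof", "fixed"],
    )
    callset = DsnpCallset(table=table, n_samples=gm.n_samples)
    detect_fixed(callset, cfg)
    return callset


def detect_fixed(callset: DsnpCallset, cfg: RunConfig) -> pd.DataFrame:
    """Flag fixed dSNPs: DAF exactly 1 with callrate >= the configured floor.

    Mutates the callset's ``fixed`` column in place and returns the fixed
    subset. The callrate floor guards against calling a site "fixed" off a
    handful of genotypes; set it to 0 for a frequency-only rule.
    """
    t = callset.table
    if len(t) == 0:
        return t
    callrate = t["n_called"] / callset.n_samples
    t["fixed"] = (t["daf"] == 1.0) & (callrate >= cfg.fixed_min_callrate)
    return t[t["fixed"]]


def proportions(callset: DsnpCallset, all_variants: int) -> tuple[float, float]:
    """(p_dsnp, p_lof): dSNP and LOF-dSNP counts over all detected variants."""
    if all_variants <= 0:
        raise ValueError("all_variants must be positive")
    p_dsnp = len(callset) / all_variants
    p_lof = int(callset.table["lof"].sum()) / all_variants
    return p_dsnp, p_lof


def daf_histogram(dafs: np.ndarray, width: float = 0.1) -> pd.DataFrame:
    """Histogram of DAFs in fixed-width bins over [0, 1] (last bin closed)."""
    edges = np.arange(0.0, 1.0 + width / 2, width)
    counts, _ = np.histogram(np.asarray(dafs, dtype=float), bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
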