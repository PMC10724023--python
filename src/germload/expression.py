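"""Expression profiling of deleterious genes from a TPM matrix.

A gene counts as expressed when its TPM reaches the configured threshold
(default 1.0) in at least the configured number of samples (default 1).
The headline statistics are the fraction of dSNPs whose gene is expressed
and the mean TPM per expressed deleterious gene per sample.
"""

from __future__ import annotations

import logging

import pandas as pd

from .classify import DsnpCallset
from .config import RunConfig

logger = logging.getLogger(__name__)


def expressed_genes(tpm: pd.DataFrame, cfg: RunConfig) -> set[str]:
    """Genes with TPM >= cfg.tpm_expressed_min in >= the required samples."""
    hits = (tpm >= cfg.tpm_expressed_min).sum(axis=1)
    return set(tpm.index[hits >= cfg.tpm_expressed_min_samples])


def expressed_dsnp_fraction(
    callset: DsnpCallset, tpm: pd.DataFrame, cfg: RunConfig
) -> float:
    """Fraction of dSNPs located in expressed deleterious genes.

    With ``cfg.expression_weighting == "dsnp"`` (default) every dSNP counts
    once; ``"gene"`` weights each deleterious gene once instead. dSNPs
    without a gene, or in genes absent from the TPM matrix, count as not
    expressed but stay in the denominator.
    """
    if len(callset) == 0:
        raise ValueError("empty deleterious callset")
    expressed = expressed_genes(tpm, cfg)
    genes = callset.table["gene_id"]
    known = genes.dropna().unique()
    absent = set(known) - set(tpm.index)
    if absent:
        logger.warning(
            "%d deleterious gene(s) absent from TPM matrix; treated as not expressed",
            len(absent),
        )
    if cfg.expression_weighting == "gene":
        if len(known) == 0:
            return 0.0
        return sum(g in expressed for g in known) / len(known)
    if cfg.expression_weighting != "dsnp":
        raise ValueError(f"unknown expression_weighting {cfg.expression_weighting!r}")
    return float(genes.isin(expressed).sum()) / len(callset)


def mean_tpm_per_gene_sample(gene_ids: set[str], tpm: pd.DataFrame) -> float:
    """Total TPM over the gene set and all samples / (genes x samples)."""
    genes = sorted(gene_ids & set(tpm.index))
    if not genes:
        raise ValueError("no genes from the set are present in the TPM matrix")
    block = tpm.loc[genes]
    return float(block.to_numpy().sum() / block.size)


def expression_summary(
    callset: DsnpCallset, tpm: pd.DataFrame, cfg: RunConfig
) -> dict[str, float]:
    """One-row summary of deleterious-gene expression for a collection."""
    expressed = expressed_genes(tpm, cfg)
    del_genes = set(callset.table["gene_id"].dropna().unique())
    expressed_del = del_genes & expressed
    frac = expressed_dsnp_fraction(callset, tpm, cfg)
    mean_tpm = (
        mean_tpm_per_gene_sample(expressed_del, tpm) if expressed_del else float("nan")
    )
    return {
        "expressed_dsnp_fraction": frac,
        "n_deleterious_genes": len(del_genes),
        "n_expressed_deleterious_genes": len(expressed_del),
        "mean_tpm_per_gene_sample": mean_tpm,
        "tpm_expressed_min": cfg.tpm_expressed_min,
    }
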