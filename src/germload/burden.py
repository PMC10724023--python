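"""Per-sample mutation burden and deleterious base-substitution rates.

Burden is measured per deleterious locus: for each sample, the fraction of
its callable deleterious loci at which it is heterozygous (burden_het) or
homozygous derived (burden_hom); the total is their sum. This count-of-loci
definition makes the decomposition total = het + hom exact. An
allele-dosage variant ((het + 2*hom) / (2*callable)) is available via
``burden_mode="alleles"``; it preserves the same additive identity with the
components rescaled to allele units.

dBSM (deleterious base-substitution mutations per sample) normalises a
deleterious-site count by genome length and sample number:
dBSM = count / (G * N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .io_formats import MISSING, GenotypeMatrix


def sample_burden(
    dosages: np.ndarray,
    mode: str = "loci",
    n_loci_denominator: int | None = None,
) -> tuple[float, float, float]:
    """Burden components for one sample over its deleterious loci.

    Parameters
    ----------
    dosages:
        Derived-allele dosages at deleterious loci (-1 = missing).
    mode:
        ``"loci"`` (default) counts carrier loci; ``"alleles"`` counts
        derived alleles over twice the callable loci.
    n_loci_denominator:
        Override the denominator (collection-wide locus count) instead of
        the sample's own callable loci.

    Returns
    -------
    (burden_het, burden_hom, burden_total)
    """
    dosages = np.asarray(dosages)
    called = dosages != MISSING
    n_callable = int(called.sum())
    if n_callable == 0:
        raise ValueError("sample has no callable deleterious loci")
    denom_loci = n_callable if n_loci_denominator is None else int(n_loci_denominator)
    if denom_loci <= 0:
        raise ValueError("denominator must be positive")
    n_het = int((dosages == 1).sum())
    n_hom = int((dosages == 2).sum())
    if mode == "loci":
        het = n_het / denom_loci
        hom = n_hom / denom_loci
    elif mode == "alleles":
        het = n_het / (2 * denom_loci)
        hom = 2 * n_hom / (2 * denom_loci)
    else:
        raise ValueError(f"unknown burden mode {mode!r}")
    return het, hom, het + hom


def burden_table(
    gm: GenotypeMatrix,
    deleterious_keys: list[str],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-sample burden table over the deleterious loci.

    One row per sample: n_het, n_hom, n_callable, burden_het, burden_hom,
    burden_total. Samples with zero callable deleterious loci raise.
    """
    cfg = cfg or RunConfig()
    sub = gm.subset(deleterious_keys)
    collection_denom = (
        len(deleterious_keys) if cfg.burden_denominator == "collection" else None
    )
    rows = []
    for i, sid in enumerate(sub.sample_ids):
        dos = sub.dosage[i]
        het, hom, total = sample_burden(
            dos, mode=cfg.burden_mode, n_loci_denominator=collection_denom
        )
        rows.append(
            {
                "sample_id": sid,
                "n_het": int((dos == 1).sum()),
                "n_hom": int((dos == 2).sum()),
                "n_callable": int((dos != MISSING).sum()),
                "burden_het": het,
                "burden_hom": hom,
                "burden_total": total,
            }
        )
    return pd.DataFrame(rows)


def collection_burden(table: pd.DataFrame) -> dict[str, float]:
    """Unweighted arithmetic means of the burden components over samples."""
    if len(table) == 0:
        raise ValueError("burden table is empty")
    return {
        "mean_burden_het": float(table["burden_het"].mean()),
        "mean_burden_hom": float(table["burden_hom"].mean()),
        "mean_burden_total": float(table["burden_total"].mean()),
    }


@dataclass(frozen=True)
class DbsmEstimate:
    """dBSM rates for one collection, for all dSNPs and the fixed subset."""

    dsnp_count: int
    fixed_count: int
    genome_length_bp: float
    n_samples: int
    dbsm_dsnp: float
    dbsm_fixed: float

    def __post_init__(self) -> None:
        if self.fixed_count > self.dsnp_count:
            raise ValueError("fixed_count cannot exceed dsnp_count")


def dbsm(count: int, genome_length_bp: float, n_samples: int) -> float:
    """Deleterious base substitutions per site per sample: count / (G * N)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if genome_length_bp <= 0 or n_samples <= 0:
        raise ValueError("genome length and sample count must be positive")
    return count / (genome_length_bp * n_samples)


def dbsm_estimate(
    dsnp_count: int,
    fixed_count: int,
    genome_length_bp: float,
    n_samples: int,
) -> DbsmEstimate:
    return DbsmEstimate(
        dsnp_count=dsnp_count,
        fixed_count=fixed_count,
        genome_length_bp=genome_length_bp,
        n_samples=n_samples,
        dbsm_dsnp=dbsm(dsnp_count, genome_length_bp, n_samples),
        dbsm_fixed=dbsm(fixed_count, genome_length_bp, n_samples),
    )


def dbsm_trend(
    dbsm_values: np.ndarray, bin_midpoints: np.ndarray
) -> tuple[float, float]:
    """Least-squares slope and intercept of dBSM against storage-year bins."""
    y = np.asarray(dbsm_values, dtype=float)
    x = np.asarray(bin_midpoints, dtype=float)
    if x.size != y.size:
        raise ValueError("value and midpoint lengths differ")
    if x.size < 2:
        raise ValueError("trend needs at least two storage-year bins")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
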