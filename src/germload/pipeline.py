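"""End-to-end orchestration: one collection in, all summary tables out.

This is the glue the CLI and the reproduction script share; each stage is a
thin call into the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import burden_table, collection_burden, dbsm_estimate
from .classify import DsnpCallset, build_callset, daf_histogram, proportions
from .config import RunConfig
from .contrasts import (
    GroupData,
    burden_association,
    paired_group_contrast,
    unique_shared_dsnps,
)
from .dfe import DfeFit, build_sfs, fit_dfe
from .expression import expression_summary
from .io_formats import GenotypeMatrix, VariantAnnotation, metadata_frame


@dataclass
class CollectionResult:
    """All collection-level summaries for one run."""

    callset: DsnpCallset
    n_variants: int
    p_dsnp: float
    p_lof: float
    fixed_count: int
    burden: pd.DataFrame
    burden_means: dict[str, float]
    dbsm_dsnp: float
    dbsm_fixed: float
    expression: dict[str, float] | None
    dfe_fit: DfeFit | None


def analyse_collection(
    gm: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    cfg: RunConfig,
    tpm: pd.DataFrame | None = None,
    fit_alpha: bool = True,
) -> CollectionResult:
    """Classify, measure burden, estimate dBSM, profile expression, fit DFE.

    The selected SFS is built from the deleterious loci; the neutral
    reference SFS from synonymous variants (the standard putatively neutral
    class).
    """
    callset = build_callset(gm, annotations, cfg)
    p_dsnp, p_lof = proportions(callset, gm.n_variants)
    fixed_count = int(callset.table["fixed"].sum())
    burden = burden_table(gm, callset.variant_keys, cfg)
    means = collection_burden(burden)
    est = dbsm_estimate(len(callset), fixed_count, cfg.genome_length_bp, gm.n_samples)
    expression = (
        expression_summary(callset, tpm, cfg) if tpm is not None and len(callset) else None
    )
    dfe_fit = None
    if fit_alpha and len(callset):
        neutral_keys = [
            a.key for a in annotations if a.consequence == "synonymous_variant"
        ]
        polymorphic = _polymorphic(gm, callset.variant_keys)
        neutral_poly = _polymorphic(gm, neutral_keys)
        if polymorphic and neutral_poly:
            sel_sfs = build_sfs(gm, polymorphic, cfg.sfs_min_retention, "selected")
            neu_sfs = build_sfs(gm, neutral_poly, cfg.sfs_min_retention, "neutral")
            if neu_sfs.n_chromosomes != sel_sfs.n_chromosomes:
                n_common = min(neu_sfs.n_chromosomes, sel_sfs.n_chromosomes)
                sel_sfs = _reproject(gm, polymorphic, n_common, "selected")
                neu_sfs = _reproject(gm, neutral_poly, n_common, "neutral")
            dfe_fit = fit_dfe(sel_sfs, neu_sfs, cfg, seed=cfg.seed)
    return CollectionResult(
        callset=callset,
        n_variants=gm.n_variants,
        p_dsnp=p_dsnp,
        p_lof=p_lof,
        fixed_count=fixed_count,
        burden=burden,
        burden_means=means,
        dbsm_dsnp=est.dbsm_dsnp,
        dbsm_fixed=est.dbsm_fixed,
        expression=expression,
        dfe_fit=dfe_fit,
    )


def _polymorphic(gm: GenotypeMatrix, keys: list[str]) -> list[str]:
    """Keys of sites carrying at least one called derived allele."""
    out = []
    sub = gm.subset(keys) if keys else None
    if sub is None:
        return out
    for j, key in enumerate(sub.variant_keys):
        col = sub.dosage[:, j]
        called = col != -1
        if called.any() and col[called].sum() > 0:
            out.append(key)
    return out


def _reproject(gm: GenotypeMatrix, keys: list[str], n_target: int, label: str):
    """Force a build_sfs projection to a given chromosome count."""
    from scipy import stats as _st

    from .dfe import SFS
    from .io_formats import MISSING

    sub = gm.subset(keys)
    called = sub.dosage != MISSING
    k = np.where(called, sub.dosage, 0).sum(axis=0)
    m = 2 * called.sum(axis=0)
    counts = np.zeros(n_target - 1)
    fixed = 0
    j = np.arange(1, n_target)
    for ki, mi in zip(k, m):
        if ki == mi:
            fixed += 1
        elif mi >= n_target:
            if mi == n_target:
                if 1 <= ki <= n_target - 1:
                    counts[ki - 1] += 1.0
            else:
                counts += _st.hypergeom.pmf(j, mi, ki, n_target)
    return SFS(n_target, counts, fixed, label)


def storage_year_groups(
    metadata: pd.DataFrame, long_min: float = 25.0, short_max: float = 20.0
) -> tuple[list[str], list[str]]:
    """Sample IDs for the longer-stored (SY2) vs shorter-stored (SY1) split."""
    long_ids = list(metadata.index[metadata["storage_years"] >= long_min])
    short_ids = list(metadata.index[metadata["storage_years"] <= short_max])
    return long_ids, short_ids


def run_contrast(
    gm: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    ids_a: list[str],
    ids_b: list[str],
    cfg: RunConfig,
    contrast_kind: str = "storage",
    labels: tuple[str, str] = ("A", "B"),
    fit_alpha: bool = False,
):
    """Paired contrast between two sample subsets of one collection."""
    results = {}
    groups = {}
    for label, ids in zip(labels, (ids_a, ids_b)):
        idx = [gm.sample_ids.index(s) for s in ids]
        sub = GenotypeMatrix(
            [gm.sample_ids[i] for i in idx], gm.variant_keys, gm.dosage[idx]
        )
        res = analyse_collection(sub, annotations, cfg, fit_alpha=fit_alpha)
        groups[label] = GroupData(
            label=label,
            burdens=res.burden["burden_total"].to_numpy(),
            dsnp_count=len(res.callset),
            variant_count=res.n_variants,
            alpha=res.dfe_fit.alpha_dfe if res.dfe_fit else None,
            dsnp_keys=frozenset(res.callset.variant_keys),
        )
        results[label] = res
    contrast = paired_group_contrast(
        groups[labels[0]],
        groups[labels[1]],
        contrast_kind=contrast_kind,
        test=cfg.contrast_test,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )
    unique_a, unique_b, shared = unique_shared_dsnps(
        groups[labels[0]].dsnp_keys, groups[labels[1]].dsnp_keys
    )
    return contrast, (unique_a, unique_b, shared), results


def write_manifest(path: str | Path, cfg: RunConfig, extra: dict | None = None) -> None:
    """Run manifest: seed, thresholds, package version."""
    manifest = {"package": "germload", "version": __version__, "config": cfg.to_dict()}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


__all__ = [
    "CollectionResult",
    "analyse_collection",
    "storage_year_groups",
    "run_contrast",
    "write_manifest",
    "daf_histogram",
]
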