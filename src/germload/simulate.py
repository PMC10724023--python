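"""Synthetic germplasm collections with genebank-like statistical structure.

The generator emulates the features the downstream analysis depends on, at
desk scale rather than transcriptome scale:

* 70-sample collections of diploid biallelic SNPs;
* a derived-allele-frequency (DAF) model mixing a rare-skewed continuous
  component (Beta(0.3, 2.5) by default, so most deleterious sites sit at
  DAF <= 0.2) with a small point mass at 1.0 for fixed sites;
* genotypes drawn per site with inbreeding coefficient F, so heterozygote
  probability 2p(1-p)(1-F) — selfing collections (F ~ 0.95) carry their
  burden mostly as homozygotes, outcrossing ones (F ~ 0.05) as
  heterozygotes;
* SIFT / GERP-RS scores consistent with each site's planted deleterious
  label (optionally noised);
* a zero-inflated log-normal TPM matrix with a silenced-gene fraction;
* genebank passport metadata, with an optional planted storage-year effect
  on burden, implemented by promoting zero-dosage deleterious genotypes to
  heterozygous carriers in older samples so that the expected extra burden
  grows linearly with storage years.

Everything derives from one seed; identical specs produce byte-identical
outputs. There is no linkage and no forward-in-time dynamics of storage or
regeneration — planted effects are marginal associations, which is exactly
what the contrast layer is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import dfe as dfe_mod
from .io_formats import (
    MISSING,
    AccessionMetadata,
    GenotypeMatrix,
    VariantAnnotation,
)

_LOF_TERMS = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "frameshift_variant",
)
_NEUTRAL_TERMS = (
    "synonymous_variant",
    "missense_variant",
    "intron_variant",
    "3_prime_UTR_variant",
    "5_prime_UTR_variant",
)


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic collection.

    Defaults describe a "genebank-like" selfing collection of 70 samples.
    ``mating_system`` maps to the inbreeding coefficient F unless
    ``inbreeding_f`` is given explicitly (selfing -> 0.95,
    outcrossing -> 0.05). Planted effects default to zero (no association).
    """

    n_samples: int = 70
    n_variants: int = 5000
    frac_deleterious: float = 0.04
    mating_system: str = "selfing"
    inbreeding_f: float | None = None
    # DAF model: mixture of a point mass at 1.0 and a rare-skewed Beta
    daf_beta_a: float = 0.3
    daf_beta_b: float = 2.5
    fixed_frac_deleterious: float = 0.02
    fixed_frac_neutral: float = 0.005
    # score model
    rs_scale_deleterious: float = 2.0
    label_noise: float = 0.0
    score_missing_rate: float = 0.0
    # genotype missingness
    missing_rate: float = 0.05
    # expression model
    n_genes: int = 500
    tpm_silent_gene_frac: float = 0.7
    tpm_zero_frac: float = 0.3
    tpm_log_mean: float = 1.5
    tpm_log_sigma: float = 1.0
    # metadata ranges
    acquisition_year_range: tuple[int, int] = (1960, 2005)
    storage_years_range: tuple[int, int] = (0, 30)
    germination_range: tuple[float, float] = (60.0, 100.0)
    # planted effects
    burden_slope_per_storage_year: float = 0.0
    alpha_delta_by_group: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not (0.0 <= self.frac_deleterious <= 1.0):
            raise ValueError("frac_deleterious must be in [0, 1]")
        f = self.effective_f
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"inbreeding coefficient F={f} outside [0, 1]")
        if self.mating_system not in ("selfing", "outcrossing"):
            raise ValueError(f"unknown mating_system {self.mating_system!r}")
        for name in ("label_noise", "score_missing_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def effective_f(self) -> float:
        if self.inbreeding_f is not None:
            return self.inbreeding_f
        return 0.95 if self.mating_system == "selfing" else 0.05


@dataclass
class SyntheticCollection:
    """Bundle returned by :func:`simulate_collection`."""

    genotypes: GenotypeMatrix
    annotations: list[VariantAnnotation]
    tpm: pd.DataFrame
    metadata: list[AccessionMetadata]
    deleterious_keys: list[str]
    spec: SimSpec


def _draw_daf(rng: np.random.Generator, n: int, spec: SimSpec, fixed_frac: float) -> np.ndarray:
    p = rng.beta(spec.daf_beta_a, spec.daf_beta_b, size=n)
    p = np.clip(p, 1e-4, 1.0 - 1e-4)
    p[rng.random(n) < fixed_frac] = 1.0
    return p


def _draw_genotypes(
    rng: np.random.Generator, p: np.ndarray, n_samples: int, f: float
) -> np.ndarray:
    """Dosage matrix (samples x sites) under inbreeding coefficient F."""
    p2 = p * p + f * p * (1.0 - p)  # hom derived
    p1 = 2.0 * p * (1.0 - p) * (1.0 - f)  # het
    u = rng.random((n_samples, p.size))
    g = np.zeros((n_samples, p.size), dtype=np.int8)
    g[u < p2[None, :] + p1[None, :]] = 1
    g[u < p2[None, :]] = 2
    return g


def simulate_collection(spec: SimSpec) -> SyntheticCollection:
    """Generate genotypes, annotations, TPM, and metadata for one collection.

    Deterministic in ``spec.seed``: the same spec yields byte-identical
    outputs. With ``label_noise == 0`` and ``score_missing_rate == 0`` the
    planted deleterious sites are exactly the sites the SIFT/RS rule
    recovers.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_samples, spec.n_variants
    n_del = int(round(L * spec.frac_deleterious))
    is_del = np.zeros(L, dtype=bool)
    is_del[rng.choice(L, size=n_del, replace=False)] = True

    daf = np.empty(L)
    daf[is_del] = _draw_daf(rng, n_del, spec, spec.fixed_frac_deleterious)
    daf[~is_del] = _draw_daf(rng, L - n_del, spec, spec.fixed_frac_neutral)

    dosage = _draw_genotypes(rng, daf, n, spec.effective_f)

    # metadata first: the planted storage effect needs storage years
    years = rng.integers(
        spec.acquisition_year_range[0], spec.acquisition_year_range[1] + 1, size=n
    )
    storage = rng.integers(
        spec.storage_years_range[0], spec.storage_years_range[1] + 1, size=n
    ).astype(float)
    regen = rng.choice([1, 2], size=n)
    germ = rng.uniform(*spec.germination_range, size=n)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    metadata = [
        AccessionMetadata(
            sample_id=sample_ids[i],
            accession_id=f"ACC{i:04d}",
            acquisition_year=int(years[i]),
            storage_years=float(storage[i]),
            regenerations=int(regen[i]),
            germination_pct=float(germ[i]),
            mating_system=spec.mating_system,
        )
        for i in range(n)
    ]

    if spec.burden_slope_per_storage_year > 0 and n_del > 0:
        # promote zero-dosage deleterious genotypes to het carriers in older
        # samples: expected extra burden per sample ~ slope * storage_years
        del_dos = dosage[:, is_del]
        zero_frac = float((del_dos == 0).mean())
        if zero_frac > 0:
            conv = np.clip(
                spec.burden_slope_per_storage_year * storage / zero_frac, 0.0, 1.0
            )
            flip = (del_dos == 0) & (rng.random(del_dos.shape) < conv[:, None])
            del_dos[flip] = 1
            dosage[:, is_del] = del_dos

    if spec.missing_rate > 0:
        dosage[rng.random(dosage.shape) < spec.missing_rate] = MISSING

    # scores consistent with (possibly noised) labels
    noisy = is_del ^ (rng.random(L) < spec.label_noise)
    sift = np.round(
        np.where(noisy, rng.uniform(0.0, 0.05, L), rng.uniform(0.0, 1.0, L)), 6
    )
    rs = np.round(
        np.where(
            noisy,
            rng.exponential(spec.rs_scale_deleterious, L) + 1e-4,
            rng.normal(0.0, 2.0, L),
        ),
        6,
    )
    # labelled-deleterious sites must pass the conjunction even after rounding
    rs[noisy & (rs <= 0)] = 1e-4
    # force non-deleterious sites to fail it
    leak = ~noisy & (sift <= 0.05) & (rs > 0)
    rs[leak] = -np.abs(rs[leak]) - 0.1
    score_missing = rng.random(L) < spec.score_missing_rate

    gene_ids = np.array([f"g{i:04d}" for i in range(spec.n_genes)])
    gene_of = rng.integers(0, spec.n_genes, size=L)
    consequences = np.where(
        noisy,
        rng.choice(
            np.array(("missense_variant",) + _LOF_TERMS),
            size=L,
            p=[0.95] + [0.05 / len(_LOF_TERMS)] * len(_LOF_TERMS),
        ),
        rng.choice(np.array(_NEUTRAL_TERMS), size=L),
    )
    alleles = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    # ancestral is REF for most sites, ALT for a fraction, exercising polarization
    aa_is_alt = rng.random(L) < 0.1

    annotations: list[VariantAnnotation] = []
    for j in range(L):
        ref, alt = alleles[ref_idx[j]], alleles[alt_idx[j]]
        annotations.append(
            VariantAnnotation(
                chrom="1",
                pos=100 * (j + 1),
                ref_allele=ref,
                alt_allele=alt,
                ancestral_allele=alt if aa_is_alt[j] else ref,
                gene_id=str(gene_ids[gene_of[j]]),
                consequence=str(consequences[j]),
                sift_score=None if score_missing[j] else float(round(sift[j], 6)),
                rs_score=None if score_missing[j] else float(round(rs[j], 6)),
            )
        )
    keys = [a.key for a in annotations]
    gm = GenotypeMatrix(sample_ids, keys, dosage)

    silent = rng.random(spec.n_genes) < spec.tpm_silent_gene_frac
    tpm_vals = rng.lognormal(spec.tpm_log_mean, spec.tpm_log_sigma, (spec.n_genes, n))
    tpm_vals[rng.random((spec.n_genes, n)) < spec.tpm_zero_frac] = 0.0
    tpm_vals[silent, :] = 0.0
    tpm = pd.DataFrame(np.round(tpm_vals, 6), index=gene_ids, columns=sample_ids)

    return SyntheticCollection(
        genotypes=gm,
        annotations=annotations,
        tpm=tpm,
        metadata=metadata,
        deleterious_keys=[keys[j] for j in range(L) if is_del[j]],
        spec=spec,
    )


def simulate_sfs(
    dfe_params: dfe_mod.DfeParams | None,
    theta: float,
    n_chromosomes: int,
    seed: int,
    quad: dfe_mod.Quadrature | None = None,
    class_label: str = "selected",
) -> dfe_mod.SFS:
    """Poisson draws around the expected SFS of a DFE (None = neutral)."""
    expected = dfe_mod.expected_sfs(dfe_params, theta, n_chromosomes, quad)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    return dfe_mod.SFS(n_chromosomes, counts, 0, class_label)


def params_with_alpha_delta(
    base: dfe_mod.DfeParams,
    delta: float,
    quad: dfe_mod.Quadrature | None = None,
) -> dfe_mod.DfeParams:
    """DFE with p_b adjusted so its alpha differs from base's by ``delta``.

    Used to plant a group-level alpha difference; solves for p_b by
    bisection (alpha is monotone in p_b).
    """
    quad = quad or dfe_mod.Quadrature()
    target = dfe_mod.alpha_from_dfe(base, quad) + delta
    if not (0.0 <= target <= 1.0):
        raise ValueError(f"target alpha {target} outside [0, 1]")

    def f(logit_p: float) -> float:
        p = 1.0 / (1.0 + np.exp(-logit_p))
        return dfe_mod.alpha_from_dfe(replace(base, p_b=p), quad) - target

    logit = optimize.brentq(f, -30.0, 30.0, xtol=1e-10)
    return replace(base, p_b=1.0 / (1.0 + np.exp(-logit)))


def simulate_group_sfs(
    spec: SimSpec,
    dfe_params: dfe_mod.DfeParams,
    theta: float,
    n_chromosomes: int,
    quad: dfe_mod.Quadrature | None = None,
) -> dict[str, tuple[dfe_mod.SFS, dfe_mod.SFS]]:
    """(selected, neutral) SFS pairs for two groups with a planted alpha gap.

    Group "A" carries the base DFE; group "B" carries a DFE whose alpha is
    shifted by ``spec.alpha_delta_by_group`` (e.g. negative to emulate a
    longer-stored group with fewer adaptive substitutions).
    """
    quad = quad or dfe_mod.Quadrature()
    params_b = (
        params_with_alpha_delta(dfe_params, spec.alpha_delta_by_group, quad)
        if spec.alpha_delta_by_group != 0.0
        else dfe_params
    )
    out = {}
    for label, params, sub in (("A", dfe_params, 1), ("B", params_b, 2)):
        sel = simulate_sfs(params, theta, n_chromosomes, spec.seed * 4 + sub, quad)
        neu = simulate_sfs(
            None, theta, n_chromosomes, spec.seed * 4 + sub + 100_000, quad, "neutral"
        )
        out[label] = (sel, neu)
    return out
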