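"""Validation harnesses: oracle checks, size/power simulations, recovery runs.

These are the package's own end-to-end checks — brute-force oracles for the
burden counter, closed-form limits for the spectrum machinery, and seeded
simulation studies of the statistical layer (test size, power against
planted effects, DFE/alpha parameter recovery). They are used by the test
suite and the reproduction script alike.
"""

from __future__ import annotations

import numpy as np

from .burden import burden_table
from .classify import build_callset
from .config import RunConfig
from .contrasts import burden_association, paired_group_contrast, permutation_pvalue
from .dfe import DfeParams, Quadrature, alpha_from_dfe, expected_sfs, fit_dfe
from .io_formats import MISSING, GenotypeMatrix, metadata_frame
from .simulate import SimSpec, simulate_collection, simulate_sfs

#: planted storage-year effect used by the power harnesses: a weak but
#: realistic drift of +0.002 burden per storage year (≈ +0.06 over a
#: 30-year shelf), and the slope that opens a ≈0.05 burden gap between the
#: >=25 yr and <=20 yr storage groups whose means differ by ≈17.5 yr.
POWER_SLOPE = 0.002
SY_SHIFT_SLOPE = 0.05 / 17.5


def brute_force_burden(dosages: np.ndarray) -> tuple[float, float, float]:
    """Per-cell reference counter, deliberately simple; the total composes
    the two component burdens, matching the additive definition."""
    het = hom = callable_ = 0
    for d in dosages:
        if d == MISSING:
            continue
        callable_ += 1
        if d == 1:
            het += 1
        elif d == 2:
            hom += 1
    return het / callable_, hom / callable_, het / callable_ + hom / callable_


def burden_oracle_match_fraction(n_matrices: int = 200, seed: int = 0) -> float:
    """Fraction of random small dosage matrices where every per-sample
    burden matches the brute-force counter exactly (bitwise)."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_matrices):
        n = int(rng.integers(2, 11))
        L = int(rng.integers(2, 21))
        dos = rng.choice([0, 1, 2], size=(n, L)).astype(np.int8)
        dos[rng.random((n, L)) < 0.10] = MISSING
        # keep every sample assayable
        for i in range(n):
            if not (dos[i] != MISSING).any():
                dos[i, 0] = 0
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)], [f"v{j}" for j in range(L)], dos
        )
        table = burden_table(gm, gm.variant_keys)
        ok = all(
            (row.burden_het, row.burden_hom, row.burden_total)
            == brute_force_burden(dos[i])
            for i, row in enumerate(table.itertuples(index=False))
        )
        matches += ok
    return matches / n_matrices


def neutral_sfs_max_rel_error(ns: tuple[int, ...] = (4, 10, 20)) -> float:
    """Worst relative error of the quadrature against theta/i."""
    quad = Quadrature()
    worst = 0.0
    for n in ns:
        e = expected_sfs(None, 1.0, n, quad)
        worst = max(worst, float(np.max(np.abs(e * np.arange(1, n) - 1.0))))
    return worst


def dfe_alpha_recovery(
    n_replicates: int = 50,
    seed: int = 0,
    theta: float = 2000.0,
    n_chromosomes: int = 20,
    params: DfeParams | None = None,
    tolerance: float = 0.05,
) -> dict[str, float]:
    """Parameter-recovery study for the DFE fit.

    Simulates selected + neutral spectra from a known DFE and refits with
    the default free model; reports the fraction of replicates whose fitted
    alpha lands within ``tolerance`` of the generating DFE's
    quadrature-computed alpha, plus the error distribution.
    """
    params = params or DfeParams(p_b=0.02, S_d_mean=-400.0, b=0.4, S_b_mean=4.0)
    quad = Quadrature()
    alpha_true = alpha_from_dfe(params, quad)
    cfg = RunConfig()
    errors = []
    for rep in range(n_replicates):
        sel = simulate_sfs(params, theta, n_chromosomes, seed=seed * 7919 + rep, quad=quad)
        neu = simulate_sfs(
            None, theta, n_chromosomes, seed=seed * 7919 + rep + 500_000,
            quad=quad, class_label="neutral",
        )
        fit = fit_dfe(sel, neu, cfg, seed=seed * 104729 + rep)
        errors.append(fit.alpha_dfe - alpha_true)
    errors = np.asarray(errors)
    return {
        "alpha_true": alpha_true,
        "fraction_within_tolerance": float((np.abs(errors) <= tolerance).mean()),
        "mean_abs_error": float(np.abs(errors).mean()),
        "median_error": float(np.median(errors)),
    }


def permutation_test_size(
    n_replicates: int = 500,
    seed: int = 0,
    n_per_group: int = 35,
    n_permutations: int = 1999,
    level: float = 0.05,
) -> float:
    """Empirical rejection rate of the permutation burden test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(0.2, 0.03, n_per_group)
        b = rng.normal(0.2, 0.03, n_per_group)
        p = permutation_pvalue(a, b, n_permutations, rng)
        rejections += p < level
    return rejections / n_replicates


def _power_spec(seed: int, slope: float) -> SimSpec:
    # smaller variant panel than the default keeps 100 replicates brisk
    # while preserving ~200 deleterious loci per collection
    return SimSpec(
        n_samples=70,
        n_variants=1000,
        frac_deleterious=0.2,
        burden_slope_per_storage_year=slope,
        seed=seed,
    )


def storage_slope_power(
    n_replicates: int = 100, seed: int = 0, slope: float = POWER_SLOPE
) -> float:
    """Fraction of replicates where the planted positive storage-year slope
    is recovered as significantly positive (two-sided p < 0.05)."""
    hits = 0
    for rep in range(n_replicates):
        coll = simulate_collection(_power_spec(seed * 6151 + rep, slope))
        table = burden_table(coll.genotypes, coll.deleterious_keys)
        res = burden_association(table, metadata_frame(coll.metadata), "storage_years")
        hits += res.slope > 0 and res.p_value < 0.05
    return hits / n_replicates


def sy_group_shift_power(
    n_replicates: int = 100, seed: int = 0, slope: float = SY_SHIFT_SLOPE
) -> float:
    """Power to detect the planted burden gap between storage-year groups.

    The slope opens a ~+0.05 mean-burden gap between the >=25 yr and
    <=20 yr groups; detection is a Welch test at p < 0.05 in the planted
    direction.
    """
    hits = 0
    for rep in range(n_replicates):
        coll = simulate_collection(_power_spec(seed * 12289 + rep, slope))
        table = burden_table(coll.genotypes, coll.deleterious_keys)
        meta = metadata_frame(coll.metadata)
        long_ids = set(meta.index[meta["storage_years"] >= 25])
        short_ids = set(meta.index[meta["storage_years"] <= 20])
        t = table.set_index("sample_id")["burden_total"]
        a = t[t.index.isin(long_ids)].to_numpy()
        b = t[t.index.isin(short_ids)].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        from scipy import stats as _st

        test = _st.ttest_ind(a, b, equal_var=False)
        hits += (a.mean() > b.mean()) and (test.pvalue < 0.05)
    return hits / n_replicates


def generator_fidelity(seed: int = 0) -> dict[str, float]:
    """Headline generator checks: rare-DAF majority, selfing extreme,
    determinism of regenerated output."""
    cfg = RunConfig()
    coll = simulate_collection(SimSpec(seed=seed))
    callset = build_callset(coll.genotypes, coll.annotations, cfg)
    frac_rare = float((callset.table["daf"] <= 0.2).mean())
    selfed = simulate_collection(SimSpec(n_samples=30, n_variants=600,
                                         inbreeding_f=1.0, seed=seed))
    het_at_f1 = int((selfed.genotypes.dosage == 1).sum())
    again = simulate_collection(SimSpec(seed=seed))
    identical = bool(
        np.array_equal(coll.genotypes.dosage, again.genotypes.dosage)
        and coll.annotations == again.annotations
        and coll.tpm.equals(again.tpm)
        and coll.metadata == again.metadata
    )
    return {
        "rare_daf_fraction": frac_rare,
        "heterozygotes_at_full_selfing": het_at_f1,
        "deterministic_rerun": float(identical),
    }
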