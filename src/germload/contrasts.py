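"""Associations and paired-group contrasts across conservation covariates.

Two layers of evidence: (i) ordinary least-squares association of each
sample's total burden with a passport covariate (acquisition year, storage
years, germination); (ii) paired contrasts between sample groups split on a
covariate threshold (longer vs shorter storage, 2 vs 1 regenerations, high
vs low germination), comparing the dSNP proportion (two-proportion z-test),
mean total burden (Welch t or seeded permutation test), and the fitted
alpha (delta reported; significance is opt-in via bootstrap elsewhere).
Stars mark p < 0.05 / 0.01 / 0.001; no multiple-testing correction is
applied by default (a Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 levels."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class AssociationResult:
    """OLS association of per-sample total burden with one covariate."""

    covariate: str
    slope: float
    intercept: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def burden_association(
    burden: pd.DataFrame, metadata: pd.DataFrame, covariate: str
) -> AssociationResult:
    """Regress burden_total on a metadata covariate (two-sided slope test).

    ``burden`` is a per-sample burden table with ``sample_id`` and
    ``burden_total``; ``metadata`` is indexed by sample_id.
    """
    merged = burden.set_index("sample_id").join(metadata[[covariate]], how="inner")
    merged = merged.dropna(subset=["burden_total", covariate])
    if len(merged) < 3:
        raise ValueError("need at least 3 samples with covariate present")
    x = merged[covariate].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    y = merged["burden_total"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(
        covariate=covariate,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        n=len(merged),
    )


@dataclass
class GroupData:
    """Per-group inputs to a paired contrast.

    burdens: per-sample total burdens; dsnp_count / variant_count feed the
    two-proportion test; alpha is the group's fitted adaptive proportion
    (optional); dsnp_keys enable unique/shared set counts.
    """

    label: str
    burdens: np.ndarray
    dsnp_count: int
    variant_count: int
    alpha: float | None = None
    dsnp_keys: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.burdens = np.asarray(self.burdens, dtype=float)
        if self.variant_count <= 0:
            raise ValueError("variant_count must be positive")
        if not (0 <= self.dsnp_count <= self.variant_count):
            raise ValueError("dsnp_count must be in [0, variant_count]")


#: expected sign of (stressed group - reference group) per metric, by contrast
EXPECTED_DIRECTIONS = {
    # stressed = longer storage: more dSNPs, more burden, less adaptive
    "storage": {"dsnp_proportion": 1, "total_burden": 1, "alpha": -1},
    # stressed = fewer regenerations (group A = 2 regenerations is relieved)
    "regeneration": {"dsnp_proportion": -1, "total_burden": -1, "alpha": 1},
    # group A = high germination: fewer dSNPs, less burden, more adaptive
    "germination": {"dsnp_proportion": -1, "total_burden": -1, "alpha": 1},
}


@dataclass
class ContrastResult:
    """Paired-group deltas (A - B), tests, and direction-vs-expectation flags."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    delta_dsnp_proportion: float
    p_dsnp_proportion: float
    delta_total_burden: float
    p_total_burden: float | None
    delta_alpha: float | None
    expected_dsnp_direction: bool | None
    expected_burden_direction: bool | None
    expected_alpha_direction: bool | None
    stars_dsnp: str
    stars_burden: str
    burden_testable: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def permutation_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Uses the add-one estimator (1 + #{|T*| >= |T|}) / (R + 1), which is
    exact-level for exchangeable data.
    """
    rng = rng or np.random.default_rng()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = a.size
    perms = np.tile(pooled, (n_permutations, 1))
    perms = rng.permuted(perms, axis=1)
    t = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    return float((1 + np.sum(np.abs(t) >= abs(observed) - 1e-12)) / (n_permutations + 1))


def _expected_flag(delta: float | None, sign: int) -> bool | None:
    if delta is None or delta == 0:
        return None
    return (delta > 0) == (sign > 0)


def paired_group_contrast(
    group_a: GroupData,
    group_b: GroupData,
    contrast_kind: str = "storage",
    test: str = "welch",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> ContrastResult:
    """Compare two sample groups on dSNP proportion, burden, and alpha.

    Group A is the conventionally "stressed" (or relieved, per
    ``contrast_kind``) group; direction flags record whether each observed
    delta matches the expected sign for that contrast. Burden comparison
    with fewer than 2 samples per group is flagged untestable rather than
    raising.
    """
    if contrast_kind not in EXPECTED_DIRECTIONS:
        raise ValueError(f"unknown contrast kind {contrast_kind!r}")
    expect = EXPECTED_DIRECTIONS[contrast_kind]

    prop_a = group_a.dsnp_count / group_a.variant_count
    prop_b = group_b.dsnp_count / group_b.variant_count
    delta_prop = prop_a - prop_b
    if delta_prop == 0.0:
        p_prop = 1.0
    else:
        _, p_prop = proportions_ztest(
            [group_a.dsnp_count, group_b.dsnp_count],
            [group_a.variant_count, group_b.variant_count],
        )
        p_prop = float(p_prop)

    delta_burden = float(group_a.burdens.mean() - group_b.burdens.mean())
    burden_testable = group_a.burdens.size >= 2 and group_b.burdens.size >= 2
    p_burden: float | None = None
    if burden_testable:
        if delta_burden == 0.0:
            p_burden = 1.0
        elif test == "welch":
            p_burden = float(
                stats.ttest_ind(group_a.burdens, group_b.burdens, equal_var=False).pvalue
            )
        elif test == "permutation":
            p_burden = permutation_pvalue(
                group_a.burdens,
                group_b.burdens,
                n_permutations,
                np.random.default_rng(seed),
            )
        else:
            raise ValueError(f"unknown test {test!r}")

    delta_alpha = (
        group_a.alpha - group_b.alpha
        if group_a.alpha is not None and group_b.alpha is not None
        else None
    )
    return ContrastResult(
        label_a=group_a.label,
        label_b=group_b.label,
        n_a=group_a.burdens.size,
        n_b=group_b.burdens.size,
        delta_dsnp_proportion=delta_prop,
        p_dsnp_proportion=p_prop,
        delta_total_burden=delta_burden,
        p_total_burden=p_burden,
        delta_alpha=delta_alpha,
        expected_dsnp_direction=_expected_flag(delta_prop, expect["dsnp_proportion"]),
        expected_burden_direction=_expected_flag(delta_burden, expect["total_burden"]),
        expected_alpha_direction=_expected_flag(delta_alpha, expect["alpha"]),
        stars_dsnp=stars(p_prop),
        stars_burden=stars(p_burden) if p_burden is not None else "",
        burden_testable=burden_testable,
    )


def unique_shared_dsnps(
    keys_a: set[str] | frozenset, keys_b: set[str] | frozenset
) -> tuple[int, int, int]:
    """(unique to A, unique to B, shared) dSNP counts between two callsets."""
    a, b = set(keys_a), set(keys_b)
    shared = a & b
    return len(a - shared), len(b - shared), len(shared)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (opt-in; raw stars are default)."""
    return list(multipletests(pvalues, method="fdr_bh")[1])
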