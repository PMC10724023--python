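"""Burden-covariate associations and paired-group contrast machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germload as gl


def burden_frame(values):
    return pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(values))], "burden_total": values}
    )


def meta_frame(**columns):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], **columns})
    return df.set_index("sample_id")


class TestBurdenAssociation:
    def test_hand_least_squares(self):
        res = gl.burden_association(
            burden_frame([0.1, 0.2, 0.3]), meta_frame(storage_years=[10, 20, 30]),
            "storage_years",
        )
        assert res.slope == pytest.approx(0.01)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.n == 3

    def test_constant_burden_zero_slope(self):
        res = gl.burden_association(
            burden_frame([0.2, 0.2, 0.2, 0.2]),
            meta_frame(storage_years=[5, 10, 15, 20]),
            "storage_years",
        )
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_covariate_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            gl.burden_association(
                burden_frame([0.1, 0.2, 0.3]), meta_frame(storage_years=[7, 7, 7]),
                "storage_years",
            )

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            gl.burden_association(
                burden_frame([0.1, 0.2]), meta_frame(storage_years=[1, 2]),
                "storage_years",
            )

    def test_planted_storage_slope_detected(self):
        coll = gl.simulate_collection(
            gl.SimSpec(burden_slope_per_storage_year=0.002, seed=31)
        )
        table = gl.burden_table(coll.genotypes, coll.deleterious_keys)
        meta = gl.metadata_frame(coll.metadata)
        res = gl.burden_association(table, meta, "storage_years")
        assert res.slope > 0
        assert res.p_value < 0.05


def group(label, burdens, dsnp=50, total=1000, alpha=None, keys=()):
    return gl.GroupData(
        label=label, burdens=np.asarray(burdens, dtype=float), dsnp_count=dsnp,
        variant_count=total, alpha=alpha, dsnp_keys=frozenset(keys),
    )


class TestPairedGroupContrast:
    def test_identical_groups_null(self):
        g = group("A", [0.1, 0.2, 0.3], alpha=0.9)
        res = gl.paired_group_contrast(g, group("B", [0.1, 0.2, 0.3], alpha=0.9))
        assert res.delta_dsnp_proportion == 0.0
        assert res.delta_total_burden == 0.0
        assert res.delta_alpha == 0.0
        assert res.stars_dsnp == "" and res.stars_burden == ""

    def test_label_swap_negates_deltas_preserves_pvalues(self):
        a = group("A", [0.30, 0.32, 0.29, 0.31], dsnp=80, alpha=0.92)
        b = group("B", [0.20, 0.22, 0.19, 0.21], dsnp=40, alpha=0.95)
        fwd = gl.paired_group_contrast(a, b)
        rev = gl.paired_group_contrast(b, a)
        assert fwd.delta_total_burden == pytest.approx(-rev.delta_total_burden)
        assert fwd.delta_dsnp_proportion == pytest.approx(-rev.delta_dsnp_proportion)
        assert fwd.delta_alpha == pytest.approx(-rev.delta_alpha)
        assert fwd.p_total_burden == pytest.approx(rev.p_total_burden)
        assert fwd.p_dsnp_proportion == pytest.approx(rev.p_dsnp_proportion)

    def test_direction_flags_follow_storage_expectation(self):
        """Longer-stored group with more dSNPs/burden, less alpha = expected."""
        a = group("SY2", [0.30, 0.31, 0.29], dsnp=80, alpha=0.92)
        b = group("SY1", [0.20, 0.21, 0.19], dsnp=40, alpha=0.95)
        res = gl.paired_group_contrast(a, b, contrast_kind="storage")
        assert res.expected_dsnp_direction is True
        assert res.expected_burden_direction is True
        assert res.expected_alpha_direction is True
        # the same deltas are "unexpected" under the regeneration reasoning
        res2 = gl.paired_group_contrast(a, b, contrast_kind="regeneration")
        assert res2.expected_burden_direction is False

    def test_small_group_flagged_untestable(self):
        res = gl.paired_group_contrast(group("A", [0.3]), group("B", [0.1, 0.2]))
        assert not res.burden_testable
        assert res.p_total_burden is None

    def test_permutation_matches_welch_qualitatively(self):
        rng = np.random.default_rng(8)
        a = group("A", rng.normal(0.3, 0.02, 20))
        b = group("B", rng.normal(0.2, 0.02, 20))
        w = gl.paired_group_contrast(a, b, test="welch")
        p = gl.paired_group_contrast(a, b, test="permutation",
                                     n_permutations=999, seed=1)
        assert w.p_total_burden < 0.001
        assert p.p_total_burden < 0.01

    def test_permutation_null_pvalue_not_extreme(self):
        rng = np.random.default_rng(9)
        p = gl.permutation_pvalue(
            rng.normal(0, 1, 15), rng.normal(0, 1, 15), 999,
            np.random.default_rng(2),
        )
        assert p > 0.05


class TestUniqueShared:
    def test_set_algebra(self):
        assert gl.unique_shared_dsnps({"a", "b", "c"}, {"b", "c", "d", "e"}) == (1, 2, 2)
        assert gl.unique_shared_dsnps({"a"}, {"a"}) == (0, 0, 1)
        assert gl.unique_shared_dsnps({"a", "b"}, {"c"}) == (2, 1, 0)

    @settings(max_examples=100, derandomize=True)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_partition_invariant(self, a, b):
        ua, ub, shared = gl.unique_shared_dsnps(
            {str(x) for x in a}, {str(x) for x in b}
        )
        assert ua + shared == len(a)
        assert ub + shared == len(b)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (1.0, "")],
    )
    def test_levels(self, p, expected):
        assert gl.stars(p) == expected

    def test_invalid_pvalue(self):
        with pytest.raises(ValueError):
            gl.stars(1.5)


def test_run_contrast_on_generated_collection(cfg):
    coll = gl.simulate_collection(
        gl.SimSpec(n_samples=30, n_variants=600, frac_deleterious=0.1,
                   burden_slope_per_storage_year=0.004, seed=17)
    )
    meta = gl.metadata_frame(coll.metadata)
    long_ids, short_ids = gl.storage_year_groups(meta)
    res, (ua, ub, shared), _ = gl.run_contrast(
        coll.genotypes, coll.annotations, long_ids, short_ids, cfg,
        "storage", ("SY2", "SY1"),
    )
    assert res.n_a == len(long_ids) and res.n_b == len(short_ids)
    assert res.delta_total_burden > 0  # planted effect direction
    assert ua >= 0 and ub >= 0 and shared >= 0


def test_bh_adjust_monotone():
    from germload.contrasts import bh_adjust

    raw = [0.001, 0.02, 0.04, 0.5]
    adj = bh_adjust(raw)
    assert all(a >= r for a, r in zip(adj, raw))
    assert adj == sorted(adj)
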