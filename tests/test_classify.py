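"""dSNP classification rule, DAF computation, fixed-site detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germload as gl
from germload.io_formats import MISSING, VariantAnnotation


def ann(sift=None, rs=None, consequence="missense_variant"):
    return VariantAnnotation(
        chrom="1", pos=100, ref_allele="A", alt_allele="G",
        ancestral_allele="A", gene_id="g1", consequence=consequence,
        sift_score=sift, rs_score=rs,
    )


class TestClassifyDsnp:
    @pytest.mark.parametrize(
        "sift,rs,expected",
        [
            (0.03, 2.1, True),    # both lines of evidence agree
            (0.05, 0.0, False),   # RS must strictly exceed 0
            (0.05, 0.001, True),  # SIFT boundary is inclusive
            (0.051, 5.0, False),
            (0.01, None, False),  # conjunction requires both scores
            (None, 3.0, False),
            (None, None, False),
        ],
    )
    def test_rule(self, cfg, sift, rs, expected):
        assert gl.classify_dsnp(ann(sift, rs), cfg) is expected

    @settings(max_examples=200, derandomize=True)
    @given(
        sift=st.floats(0, 1),
        rs=st.floats(-10, 10),
        tighter_sift=st.floats(0, 0.05),
        higher_rs=st.floats(0, 5),
    )
    def test_monotone_in_thresholds(self, sift, rs, tighter_sift, higher_rs):
        """Lowering sift_max or raising rs_min never adds dSNPs."""
        loose = gl.RunConfig()
        tight = gl.RunConfig(sift_max=tighter_sift, rs_min=higher_rs)
        a = ann(sift, rs)
        if gl.classify_dsnp(a, tight):
            assert gl.classify_dsnp(a, loose)


class TestIsLof:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("stop_gained", True),
            ("splice_donor_variant", True),
            ("frameshift_variant", True),
            ("synonymous_variant", False),
            ("missense_variant", False),
        ],
    )
    def test_membership(self, cfg, term, expected):
        assert gl.is_lof(ann(consequence=term), cfg) is expected

    def test_unknown_term_false_with_warning(self, cfg, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert gl.is_lof(ann(consequence="weird_term"), cfg) is False
        assert "weird_term" in caplog.text


class TestDerivedAlleleFreq:
    def test_hand_count_with_missing(self):
        daf, n = gl.derived_allele_freq(np.array([0, 1, 2, MISSING]))
        assert daf == pytest.approx(0.5)
        assert n == 3

    @pytest.mark.parametrize("dosages,expected", [([2, 2, 2], 1.0), ([0, 0], 0.0)])
    def test_boundaries(self, dosages, expected):
        daf, _ = gl.derived_allele_freq(np.array(dosages))
        assert daf == expected

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="no called"):
            gl.derived_allele_freq(np.array([MISSING, MISSING]))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=1, max_size=30))
    def test_order_invariant_and_bounded(self, dosages):
        arr = np.array(dosages)
        if not (arr != MISSING).any():
            return
        daf, _ = gl.derived_allele_freq(arr)
        daf_rev, _ = gl.derived_allele_freq(arr[::-1])
        assert daf == daf_rev
        assert 0.0 <= daf <= 1.0


class TestDetectFixed:
    def _callset(self, n_fixedish, n_other, n_samples=70, callrate=1.0):
        import pandas as pd

        n_called = int(round(callrate * n_samples))
        rows = [
            {"variant_key": f"k{i}", "gene_id": "g", "sift": 0.01, "rs": 1.0,
             "daf": 1.0, "n_called": n_called, "lof": False, "fixed": False}
            for i in range(n_fixedish)
        ] + [
            {"variant_key": f"m{i}", "gene_id": "g", "sift": 0.01, "rs": 1.0,
             "daf": 0.4, "n_called": n_samples, "lof": False, "fixed": False}
            for i in range(n_other)
        ]
        columns = ["variant_key", "gene_id", "sift", "rs", "daf", "n_called", "lof", "fixed"]
        return gl.DsnpCallset(pd.DataFrame(rows, columns=columns), n_samples)

    def test_fixture_shaped_like_barley(self, cfg):
        """37 of 40 dSNPs at frequency 1 with full callrate -> 37 fixed."""
        cs = self._callset(37, 3)
        fixed = gl.detect_fixed(cs, cfg)
        assert len(fixed) == 37

    def test_callrate_floor(self, cfg):
        cs = self._callset(5, 0, callrate=0.5)
        assert len(gl.detect_fixed(cs, cfg)) == 0
        lax = gl.RunConfig(fixed_min_callrate=0.0)
        assert len(gl.detect_fixed(cs, lax)) == 5

    def test_empty_callset(self, cfg):
        cs = self._callset(0, 0)
        assert len(gl.detect_fixed(cs, cfg)) == 0


class TestProportions:
    def test_printed_scale_division(self, cfg):
        """125 dSNPs in ~2.08M variants gives the 6e-5 order of proportion."""
        cs = TestDetectFixed()._callset(0, 125)
        p_dsnp, _ = gl.proportions(cs, 2_083_333)
        assert p_dsnp == pytest.approx(0.00006, rel=1e-3)

    def test_extremes(self, cfg):
        empty = TestDetectFixed()._callset(0, 0)
        assert gl.proportions(empty, 100) == (0.0, 0.0)
        full = TestDetectFixed()._callset(0, 10)
        assert gl.proportions(full, 10)[0] == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            gl.proportions(TestDetectFixed()._callset(0, 1), 0)


def test_zero_noise_generator_recovers_planted_set(small_collection, cfg):
    """With no label noise the SIFT/RS rule recovers exactly the planted sites."""
    cs = gl.build_callset(small_collection.genotypes, small_collection.annotations, cfg)
    assert sorted(cs.variant_keys) == sorted(small_collection.deleterious_keys)


def test_daf_histogram_bins():
    hist = gl.daf_histogram(np.array([0.05, 0.15, 0.15, 0.95, 1.0]))
    assert hist["count"].sum() == 5
    assert hist.loc[1, "count"] == 2  # (0.1, 0.2]
    assert hist.loc[9, "count"] == 2  # 0.95 and 1.0 in the closed last bin
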