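"""Expected spectra, SFS construction/projection, alpha, and the DFE fit."""

import numpy as np
import pytest

import germload as gl
from germload.dfe import _poisson_ll
from germload.io_formats import MISSING, GenotypeMatrix

QUAD = gl.Quadrature()


class TestExpectedSfs:
    @pytest.mark.parametrize("n", [4, 10, 20])
    def test_neutral_watterson_law(self, n):
        e = gl.expected_sfs(None, 1.0, n, QUAD)
        np.testing.assert_allclose(e, 1 / np.arange(1, n), rtol=1e-8)

    def test_positivity(self):
        p = gl.DfeParams(p_b=0.3, S_d_mean=-100, b=0.3, S_b_mean=10)
        assert (gl.expected_sfs(p, 5.0, 12, QUAD) >= 0).all()

    def test_strong_purifying_selection_skews_spectrum(self):
        """Gamma-only deleterious DFE crushes high-frequency bins."""
        p = gl.DfeParams(p_b=0.0, S_d_mean=-50, b=1.0, S_b_mean=1.0)
        e = gl.expected_sfs(p, 1.0, 10, QUAD)
        neutral_ratio = 1 / 9
        assert e[-1] / e[0] < 0.2 * neutral_ratio

    def test_agrees_with_higher_resolution_quadrature(self):
        """Doubling both grids is the self-consistency oracle."""
        p = gl.DfeParams(p_b=0.05, S_d_mean=-50, b=0.5, S_b_mean=8)
        e1 = gl.expected_sfs(p, 100.0, 20, QUAD)
        e2 = gl.expected_sfs(p, 100.0, 20, gl.Quadrature(128, 256))
        np.testing.assert_allclose(e1, e2, rtol=1e-4)

    def test_theta_zero_gives_empty_spectrum(self):
        assert gl.expected_sfs(None, 0.0, 6, QUAD).sum() == 0.0


class TestAlphaFromDfe:
    def test_no_beneficial_mass_gives_zero(self):
        assert gl.alpha_from_dfe(gl.DfeParams(0.0, -100, 0.5, 5), QUAD) == 0.0

    def test_all_beneficial_gives_one(self):
        assert gl.alpha_from_dfe(gl.DfeParams(1.0, -100, 0.5, 5), QUAD) == 1.0

    def test_monotone_in_p_b(self):
        alphas = [
            gl.alpha_from_dfe(gl.DfeParams(p, -200, 0.4, 5), QUAD)
            for p in np.linspace(0.0, 1.0, 9)
        ]
        assert all(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:]))

    def test_symmetric_magnitudes_favor_beneficial_fixation(self):
        """r(S) > r(-S) for S > 0: equal-mass symmetric DFE gives alpha > 1/2."""
        p = gl.DfeParams(p_b=0.5, S_d_mean=-5, b=1.0, S_b_mean=5)
        assert gl.alpha_from_dfe(p, QUAD) > 0.5


class TestBuildSfs:
    def test_hand_tally_complete_data(self):
        gm = GenotypeMatrix(
            ["a", "b"], ["v1", "v2", "v3"],
            np.array([[1, 2, 2], [1, 0, 2]], dtype=np.int8),
        )
        sfs = gl.build_sfs(gm)
        assert sfs.n_chromosomes == 4
        np.testing.assert_array_equal(sfs.counts, [0, 2, 0])
        assert sfs.fixed_count == 1

    def test_no_variants_gives_zero_spectrum(self):
        gm = GenotypeMatrix(["a", "b"], [], np.zeros((2, 0), dtype=np.int8))
        sfs = gl.build_sfs(gm)
        assert sfs.counts.sum() == 0 and sfs.fixed_count == 0

    def test_complete_data_projection_is_identity(self):
        rng = np.random.default_rng(2)
        dos = rng.choice([0, 1, 2], size=(5, 30)).astype(np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(5)], [f"v{j}" for j in range(30)], dos
        )
        sfs = gl.build_sfs(gm)
        assert sfs.n_chromosomes == 10
        direct = np.zeros(9)
        fixed = 0
        for j in range(30):
            k = dos[:, j].sum()
            if k == 10:
                fixed += 1
            elif 1 <= k <= 9:
                direct[k - 1] += 1
        np.testing.assert_array_equal(sfs.counts, direct)
        assert sfs.fixed_count == fixed
        # identity projection conserves the polymorphic count mass exactly
        assert sfs.counts.sum() == sum(1 for j in range(30) if 1 <= dos[:, j].sum() <= 9)

    def test_hypergeometric_downprojection_hand_case(self):
        """One complete het site plus one half-called het site at n=2."""
        dos = np.array([[1, 1], [1, MISSING]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b"], ["v1", "v2"], dos)
        sfs = gl.build_sfs(gm)
        # retention floor forces n=2; site v1 (k=2 of m=4) contributes
        # P(j=1 | hypergeom) = C(2,1)C(2,1)/C(4,2) = 2/3; v2 maps directly
        assert sfs.n_chromosomes == 2
        np.testing.assert_allclose(sfs.counts, [1 + 2 / 3])


class TestSimulateSfs:
    def test_neutral_means_follow_one_over_i(self):
        lam = np.array([1000.0, 500.0, 1000 / 3])
        counts = np.stack(
            [gl.simulate_sfs(None, 1000.0, 4, seed=s).counts for s in range(200)]
        )
        se = np.sqrt(lam / 200)
        assert (np.abs(counts.mean(axis=0) - lam) < 3 * se).all()

    def test_theta_zero_all_zero(self):
        assert gl.simulate_sfs(None, 0.0, 6, seed=1).counts.sum() == 0

    def test_deleterious_dfe_below_neutral_everywhere(self):
        p = gl.DfeParams(0.0, -50, 0.5, 1.0)
        e_sel = gl.expected_sfs(p, 100.0, 10, QUAD)
        e_neu = gl.expected_sfs(None, 100.0, 10, QUAD)
        assert (e_sel < e_neu).all()


@pytest.fixture(scope="module")
def spectra():
    p = gl.DfeParams(p_b=0.02, S_d_mean=-400, b=0.4, S_b_mean=4)
    sel = gl.simulate_sfs(p, 2000.0, 20, seed=1000, quad=QUAD)
    neu = gl.simulate_sfs(None, 2000.0, 20, seed=5000, quad=QUAD, class_label="neutral")
    return p, sel, neu


class TestFitDfe:
    def test_deterministic_under_seed(self, spectra):
        _, sel, neu = spectra
        cfg = gl.RunConfig(n_restarts=3)
        f1 = gl.fit_dfe(sel, neu, cfg, seed=9)
        f2 = gl.fit_dfe(sel, neu, cfg, seed=9)
        assert f1.alpha_dfe == f2.alpha_dfe
        assert f1.log_likelihood == f2.log_likelihood
        assert f1.params == f2.params

    def test_fit_likelihood_beats_generating_parameters(self, spectra):
        p, sel, neu = spectra
        cfg = gl.RunConfig(n_restarts=5)
        fit = gl.fit_dfe(sel, neu, cfg, seed=1)
        inv_i = 1 / np.arange(1, 20)
        ll_true = _poisson_ll(neu.counts, 2000 * inv_i) + _poisson_ll(
            sel.counts, gl.expected_sfs(p, 2000.0, 20, QUAD)
        )
        assert fit.log_likelihood >= ll_true - 5.0  # chi-square slack
        assert fit.converged

    def test_p_b_fixed_at_zero_forces_alpha_zero(self):
        neu = gl.simulate_sfs(None, 500.0, 10, seed=3, class_label="neutral")
        sel = gl.SFS(10, neu.counts * 0.5)
        cfg = gl.RunConfig(n_restarts=3, fix_p_b=0.0)
        fit = gl.fit_dfe(sel, neu, cfg, seed=4)
        assert fit.alpha_dfe == 0.0
        assert fit.p_b == 0.0

    def test_mismatched_n_raises(self):
        a = gl.SFS(4, np.ones(3))
        b = gl.SFS(6, np.ones(5), class_label="neutral")
        with pytest.raises(ValueError):
            gl.fit_dfe(a, b)


def test_planted_alpha_delta_solver():
    base = gl.DfeParams(0.02, -400, 0.4, 4)
    shifted = gl.params_with_alpha_delta(base, -0.1, QUAD)
    a0 = gl.alpha_from_dfe(base, QUAD)
    a1 = gl.alpha_from_dfe(shifted, QUAD)
    assert a1 == pytest.approx(a0 - 0.1, abs=1e-6)
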