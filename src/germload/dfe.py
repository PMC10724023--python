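"""Site-frequency spectra and distribution-of-fitness-effects inference.

The model is a Poisson random field over derived-allele counts. For a site
under scaled selection S = 4Ns, the expected number of variants at derived
count i in a sample of n chromosomes is

    E[x_i] = theta * integral phi(S) H(S, n, i) dS

with the sojourn-time kernel

    H(S, n, i) = int_0^1 (1 - e^{-S(1-q)}) / ((1 - e^{-S}) q (1 - q))
                 * C(n, i) q^i (1-q)^{n-i} dq

and the neutral limit H(0, n, i) = 1/i (Watterson's 1/i law). phi is a
mixture DFE: with probability 1 - p_b a deleterious effect, -S ~ Gamma with
mean |S_d_mean| and shape b; with probability p_b a beneficial effect,
S ~ Exponential with mean S_b_mean.

The proportion of adaptive substitutions alpha weights the DFE by the
relative fixation rate r(S) = S / (1 - e^{-S}) (r(0) = 1):

    alpha = E[r(S); S > 0] / E[r(S)]

Fitting maximises the product-Poisson likelihood of a selected and a
neutral spectrum jointly, with log/logit transforms to unconstrained space
and seeded multi-start optimisation (DFE likelihoods are multimodal).

No nuisance distortion parameters and no divergence data are modelled: the
minimal gamma + exponential mixture keeps the fit identifiable at the
spectrum sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .config import RunConfig
from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "SFS",
    "DfeParams",
    "DfeFit",
    "Quadrature",
    "build_sfs",
    "expected_sfs",
    "alpha_from_dfe",
    "fit_dfe",
]


@dataclass(frozen=True)
class DfeParams:
    """Gamma + exponential mixture DFE over scaled selection S = 4Ns.

    p_b is the probability mass of the beneficial (S > 0) class; the
    deleterious class has mean S_d_mean (< 0) and gamma shape b; the
    beneficial class is exponential with mean S_b_mean (> 0).
    """

    p_b: float
    S_d_mean: float
    b: float
    S_b_mean: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_b <= 1.0):
            raise ValueError(f"p_b must be in [0, 1], got {self.p_b}")
        if self.S_d_mean >= 0:
            raise ValueError("S_d_mean must be negative (deleterious class)")
        if self.b <= 0:
            raise ValueError("gamma shape b must be positive")
        if self.S_b_mean <= 0:
            raise ValueError("S_b_mean must be positive (beneficial class)")


@dataclass
class SFS:
    """Folded-free (derived) site-frequency spectrum.

    ``counts[i-1]`` is the number of variants at derived count i among
    ``n_chromosomes``; entries may be fractional after hypergeometric
    projection of sites with missing genotypes. Sites at frequency 1 are
    tallied separately in ``fixed_count``.
    """

    n_chromosomes: int
    counts: np.ndarray
    fixed_count: int = 0
    class_label: str = "selected"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes")
        if self.counts.shape != (self.n_chromosomes - 1,):
            raise ValueError(
                f"counts length {self.counts.shape[0]} != n_chromosomes - 1"
            )
        if (self.counts < 0).any() or self.fixed_count < 0:
            raise ValueError("SFS counts must be nonnegative")


# ---------------------------------------------------------------------------
# quadrature machinery


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(e^x - 1) for x > 0, stable for large x."""
    x = np.asarray(x, dtype=float)
    small = x < 30.0
    out = np.where(small, np.log(np.expm1(np.where(small, x, 1.0))), 0.0)
    return np.where(small, out, x + np.log1p(-np.exp(-np.where(small, 30.0, x))))


def _sojourn_ratio(S: np.ndarray, q: np.ndarray) -> np.ndarray:
    """(1 - e^{-S(1-q)}) / (1 - e^{-S}) with the S -> 0 limit (1 - q).

    S broadcasts against q; stable for strongly negative S via log-space.
    """
    S = np.asarray(S, dtype=float)
    Sb, qb = np.broadcast_arrays(S, q)
    out = np.empty(Sb.shape, dtype=float)

    tiny = np.abs(Sb) < 1e-8
    out[tiny] = 1.0 - qb[tiny]

    pos = (Sb >= 1e-8)
    if pos.any():
        s, qq = Sb[pos], qb[pos]
        out[pos] = np.expm1(-s * (1.0 - qq)) / np.expm1(-s)

    neg = (Sb <= -1e-8)
    if neg.any():
        a = -Sb[neg]  # positive
        qq = qb[neg]
        out[neg] = np.exp(_log_expm1(a * (1.0 - qq)) - _log_expm1(a))
    return out


class Quadrature:
    """Gauss-Legendre grids for the frequency (q) and selection (S) integrals.

    q uses ``q_nodes`` points on (0, 1); the DFE expectation maps
    ``s_nodes`` points through each branch's quantile function, so the
    selection integral is exact in the density and approximates only the
    smooth kernel. Per-n binomial-sampling matrices are cached.
    """

    def __init__(self, q_nodes: int = 64, s_nodes: int = 128):
        self.q_nodes = q_nodes
        self.s_nodes = s_nodes
        xq, wq = np.polynomial.legendre.leggauss(q_nodes)
        self.q = 0.5 * (xq + 1.0)
        self.wq = 0.5 * wq
        xs, ws = np.polynomial.legendre.leggauss(s_nodes)
        self.u = 0.5 * (xs + 1.0)
        self.wu = 0.5 * ws
        self._binom_cache: dict[int, np.ndarray] = {}
        self._h0_cache: dict[int, np.ndarray] = {}

    def _binom_matrix(self, n: int) -> np.ndarray:
        """(q_nodes, n-1) matrix of C(n,i) q^i (1-q)^{n-i} / (q(1-q))."""
        if n not in self._binom_cache:
            i = np.arange(1, n)
            logq = np.log(self.q)[:, None]
            log1q = np.log1p(-self.q)[:, None]
            logC = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
            # divide by q(1-q) once here: exponents i-1 and n-i-1
            logB = logC[None, :] + (i - 1) * logq + (n - i - 1) * log1q
            self._binom_cache[n] = np.exp(logB)
        return self._binom_cache[n]

    def sojourn(self, S: np.ndarray, n: int) -> np.ndarray:
        """H(S, n, i) for a vector of S values; shape (len(S), n-1)."""
        S = np.atleast_1d(np.asarray(S, dtype=float))
        ratio = _sojourn_ratio(S[:, None], self.q[None, :])
        return (ratio * self.wq[None, :]) @ self._binom_matrix(n)

    def neutral_kernel(self, n: int) -> np.ndarray:
        """H(0, n, i) computed by the same quadrature (equals 1/i exactly
        once the q-integrand, a polynomial, is within Gauss exactness)."""
        if n not in self._h0_cache:
            self._h0_cache[n] = self.sojourn(np.array([0.0]), n)[0]
        return self._h0_cache[n]


def _branch_nodes(params: DfeParams, quad: Quadrature) -> tuple[np.ndarray, np.ndarray]:
    """Selection magnitudes at the quantile-mapped nodes of each branch."""
    s_del = stats.gamma.ppf(quad.u, a=params.b, scale=-params.S_d_mean / params.b)
    s_ben = -params.S_b_mean * np.log1p(-quad.u)  # exponential quantiles
    return s_del, s_ben


def expected_sfs(
    params: DfeParams | None,
    theta: float,
    n: int,
    quad: Quadrature | None = None,
) -> np.ndarray:
    """Expected SFS counts E[x_1..x_{n-1}] under the Poisson random field.

    ``params=None`` is the neutral point mass at S = 0, for which the exact
    expectation is theta / i.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    quad = quad or Quadrature()
    if params is None:
        return theta * quad.neutral_kernel(n)
    s_del, s_ben = _branch_nodes(params, quad)
    h_del = quad.sojourn(-s_del, n)
    e_del = quad.wu @ h_del
    if params.p_b > 0:
        e_ben = quad.wu @ quad.sojourn(s_ben, n)
    else:
        e_ben = 0.0
    expected = theta * ((1.0 - params.p_b) * e_del + params.p_b * e_ben)
    if not np.all(np.isfinite(expected)):
        raise FloatingPointError("non-finite expected SFS")
    return expected


def _fixation_rate_pos(s: np.ndarray) -> np.ndarray:
    """r(S) = S / (1 - e^{-S}) for S = s > 0 (limit 1 at 0)."""
    s = np.asarray(s, dtype=float)
    out = np.ones_like(s)
    big = s >= 1e-8
    out[big] = s[big] / (-np.expm1(-s[big]))
    return out


def _fixation_rate_neg(s: np.ndarray) -> np.ndarray:
    """r(S) for S = -s < 0: s / (e^s - 1); underflows to 0 for huge s."""
    s = np.asarray(s, dtype=float)
    out = np.ones_like(s)
    mid = (s >= 1e-8) & (s < 700.0)
    out[mid] = s[mid] / np.expm1(s[mid])
    out[s >= 700.0] = 0.0
    return out


def alpha_from_dfe(params: DfeParams, quad: Quadrature | None = None) -> float:
    """Proportion of adaptive substitutions implied by the DFE.

    alpha = E[r(S); S>0] / E[r(S)] with r(S) = S/(1 - e^{-S}); an
    all-deleterious DFE gives 0 by construction.
    """
    if params.p_b == 0.0:
        return 0.0
    if params.p_b == 1.0:
        return 1.0
    quad = quad or Quadrature()
    s_del, s_ben = _branch_nodes(params, quad)
    num = params.p_b * float(quad.wu @ _fixation_rate_pos(s_ben))
    den = num + (1.0 - params.p_b) * float(quad.wu @ _fixation_rate_neg(s_del))
    if den <= 0.0:
        return 0.0
    return min(1.0, num / den)


# ---------------------------------------------------------------------------
# SFS construction from genotypes


def build_sfs(
    gm: GenotypeMatrix,
    keys: list[str] | None = None,
    min_retention: float = 0.9,
    class_label: str = "selected",
) -> SFS:
    """Tally a derived SFS from dosages, projecting missingness down.

    Each site's derived count among called chromosomes feeds the spectrum.
    Sites with missing genotypes are projected to a common chromosome count
    n by hypergeometric expectation; n is the largest value retaining at
    least ``min_retention`` of polymorphic sites (complete data keeps
    n = 2 * n_samples and the projection is the identity). Sites at derived
    frequency 1 go to ``fixed_count``; projected mass at subsample counts 0
    and n is discarded, as unobservable.
    """
    sub = gm if keys is None else gm.subset(list(keys))
    called = sub.dosage != MISSING
    n_called = called.sum(axis=0)
    if sub.n_variants and not n_called.all():
        raise ValueError("site(s) with no called genotypes in SFS input")
    full_n = 2 * sub.n_samples
    if sub.n_variants == 0:
        return SFS(full_n, np.zeros(full_n - 1), 0, class_label)
    k = np.where(called, sub.dosage, 0).sum(axis=0)
    m = 2 * n_called
    fixed = k == m
    fixed_count = int(fixed.sum())
    k, m = k[~fixed], m[~fixed]
    if k.size == 0:
        return SFS(full_n, np.zeros(full_n - 1), fixed_count, class_label)
    # largest common chromosome count keeping >= min_retention of sites
    candidates = np.arange(2, m.max() + 1)
    retention = (m[None, :] >= candidates[:, None]).mean(axis=1)
    n_proj = int(candidates[retention >= min_retention].max())
    counts = np.zeros(n_proj - 1, dtype=float)
    j = np.arange(1, n_proj)
    for ki, mi in zip(k, m):
        if mi < n_proj:
            continue
        if mi == n_proj:
            if 1 <= ki <= n_proj - 1:
                counts[ki - 1] += 1.0
        else:
            counts += stats.hypergeom.pmf(j, mi, ki, n_proj)
    return SFS(n_proj, counts, fixed_count, class_label)


# ---------------------------------------------------------------------------
# maximum-likelihood fit


@dataclass
class DfeFit:
    """Fitted DFE mixture, mutation intensities, and derived alpha."""

    theta_neutral: float
    theta_selected: float
    params: DfeParams
    alpha_dfe: float
    log_likelihood: float
    converged: bool
    n_restarts_used: int

    @property
    def p_b(self) -> float:
        return self.params.p_b

    @property
    def S_d_mean(self) -> float:
        return self.params.S_d_mean

    @property
    def S_b_mean(self) -> float:
        return self.params.S_b_mean

    @property
    def b(self) -> float:
        return self.params.b


def _poisson_ll(x: np.ndarray, lam: np.ndarray) -> float:
    lam = np.maximum(lam, 1e-300)
    return float(np.sum(x * np.log(lam) - lam - gammaln(x + 1.0)))


_BOUNDS = {
    "log_theta": (np.log(1e-6), np.log(1e12)),
    "logit_p_b": (-13.8, 6.9),  # p_b in ~[1e-6, 0.999]
    "log_m_d": (np.log(1e-2), np.log(1e5)),
    "log_b": (np.log(0.05), np.log(20.0)),
    "log_m_b": (np.log(1e-2), np.log(1e3)),
}


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def fit_dfe(
    selected: SFS,
    neutral: SFS,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> DfeFit:
    """Joint Poisson ML fit of the DFE mixture to selected + neutral SFS.

    The neutral spectrum constrains theta_neutral through the exact 1/i
    law; the selected spectrum is fit with its own intensity and the
    gamma + exponential DFE. Optimisation runs ``cfg.n_restarts`` seeded
    L-BFGS-B starts on transformed parameters and keeps the best optimum.
    Non-convergence of every start is flagged, not raised. Fixed-class
    counts are not used (no divergence data in the model).
    """
    cfg = cfg or RunConfig()
    if selected.n_chromosomes != neutral.n_chromosomes:
        raise ValueError("selected and neutral SFS must share n_chromosomes")
    n = selected.n_chromosomes
    quad = Quadrature(cfg.q_nodes, cfg.s_nodes)
    inv_i = 1.0 / np.arange(1, n)
    x_sel = selected.counts
    x_neu = neutral.counts
    fix_p_b = cfg.fix_p_b

    def unpack(z: np.ndarray) -> tuple[float, float, DfeParams]:
        theta_n = np.exp(z[0])
        theta_s = np.exp(z[1])
        if fix_p_b is None:
            p_b = _expit(z[2])
            m_d, shape, m_b = np.exp(z[3]), np.exp(z[4]), np.exp(z[5])
        else:
            p_b = fix_p_b
            m_d, shape, m_b = np.exp(z[2]), np.exp(z[3]), np.exp(z[4])
        return theta_n, theta_s, DfeParams(p_b, -m_d, shape, m_b)

    def nll(z: np.ndarray) -> float:
        try:
            theta_n, theta_s, params = unpack(z)
            lam_sel = expected_sfs(params, theta_s, n, quad)
        except (FloatingPointError, ValueError, OverflowError):
            return 1e12
        ll = _poisson_ll(x_neu, theta_n * inv_i) + _poisson_ll(x_sel, lam_sel)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [_BOUNDS["log_theta"], _BOUNDS["log_theta"]]
    if fix_p_b is None:
        bounds.append(_BOUNDS["logit_p_b"])
    bounds += [_BOUNDS["log_m_d"], _BOUNDS["log_b"], _BOUNDS["log_m_b"]]

    # moment-style starting scales: theta from Watterson-like rescaling
    harmonic = float(np.sum(inv_i))
    theta_n0 = max(float(np.sum(x_neu)) / harmonic, 1e-3)
    theta_s0 = max(float(np.sum(x_sel)) / harmonic, 1e-3)

    rng = np.random.default_rng(seed if seed is not None else cfg.seed)
    best = None
    converged = False
    for _ in range(max(1, cfg.n_restarts)):
        z0 = [
            np.log(theta_n0) + rng.uniform(-0.5, 0.5),
            np.log(theta_s0) + rng.uniform(-0.5, 1.5),
        ]
        if fix_p_b is None:
            z0.append(np.log(10.0) * rng.uniform(-3.0, -0.5))  # logit ~ log for small p
        z0 += [
            np.log(10.0) * rng.uniform(0.5, 3.2),  # |S_d| in ~[3, 1600]
            np.log(10.0) * rng.uniform(-0.9, 0.2),  # shape in ~[0.13, 1.6]
            np.log(10.0) * rng.uniform(-0.3, 1.3),  # S_b in ~[0.5, 20]
        ]
        z0 = np.clip(np.asarray(z0), [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, z0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    theta_n, theta_s, params = unpack(best.x)
    return DfeFit(
        theta_neutral=theta_n,
        theta_selected=theta_s,
        params=params,
        alpha_dfe=alpha_from_dfe(params, quad),
        log_likelihood=-best.fun,
        converged=converged,
        n_restarts_used=max(1, cfg.n_restarts),
    )
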