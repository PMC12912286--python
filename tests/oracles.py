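"""Independent brute-force oracles used to validate the package's numerics.

These deliberately take different computational routes from the implementation:
the two-sided JZS Bayes factor is computed from the Zellner-Siow g-prior
integral (an algebraically distinct formula), the one-sided factor by plain
trapezoid quadrature over a dense effect-size grid, and OLS by explicit normal
equations.
"""

import numpy as np
from scipy import stats
from scipy.special import gammaln


def jzs_bf_two_sided_g_integral(t: float, df: int, n_eff: float, rscale: float) -> float:
    """Two-sided JZS BF10 via the g-prior mixture integral.

    BF10 = ∫ (1+N g)^{-1/2} [1 + t²/((1+N g)ν)]^{-(ν+1)/2} π(g) dg
           / (1 + t²/ν)^{-(ν+1)/2},
    with g ~ InverseGamma(1/2, rscale²/2), evaluated by trapezoid on a dense
    log-g grid.
    """
    u = np.linspace(-18.0, 18.0, 40001)  # log g
    g = np.exp(u)
    nu = df
    log_prior = (
        0.5 * np.log(rscale**2 / 2.0) - gammaln(0.5) - 1.5 * np.log(g) - rscale**2 / (2 * g)
    )
    log_lik = -0.5 * np.log1p(n_eff * g) - (nu + 1) / 2.0 * np.log1p(
        t**2 / ((1 + n_eff * g) * nu)
    )
    integrand = np.exp(log_prior + log_lik + u)  # du substitution: dg = g du
    numer = np.trapezoid(integrand, u)
    denom = (1 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return float(numer / denom)


def jzs_bf_one_sided_grid(t: float, df: int, n_eff: float, rscale: float, direction: str) -> float:
    """Directional JZS BF10 by trapezoid over a dense effect-size grid."""
    span = abs(t) / np.sqrt(n_eff) + 40.0 * rscale + 20.0 / np.sqrt(n_eff)
    delta = np.linspace(0.0, span, 200001)
    if direction == "negative":
        delta = -delta
    prior = 2.0 * stats.cauchy.pdf(delta, scale=rscale)
    lik = stats.nct.pdf(t, df, delta * np.sqrt(n_eff))
    numer = np.trapezoid(prior * lik, delta)
    if direction == "negative":
        numer = -numer  # descending grid
    return float(numer / stats.t.pdf(t, df))


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)
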