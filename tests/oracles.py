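"""Independent oracles used by the test suite.

These re-derive the package's core quantities along different routes:
a 2-D numerical quadrature of the Normal-Gamma marginal likelihood, the
sequential Student-t predictive product, a transportation-problem linear
program for EMD, and the 1-D CDF-difference closed form. None of them share
code with the implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog, minimize_scalar
from scipy.special import gammaln
from scipy.stats import t as student_t


def ng_log_marginal_quadrature(x, alpha: float, lam: float, nodes: int = 200) -> float:
    """Normal-Gamma log marginal via 2-D Gauss-Legendre quadrature.

    Integrates prod_i N(x_i | mu, 1/tau) * N(mu | 0, 1/(lam*tau)) *
    Gamma(tau | alpha, beta) over (mu, tau), with beta derived from
    (alpha, lam) the same way the scored model derives it. The integration
    uses log-tau and u = (mu - mu_hat) * sqrt(tau) coordinates so the peak
    width is constant; mu_hat is located numerically (the conditional argmax
    over mu does not depend on tau).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return 0.0
    beta = max(1.0, lam * (alpha - 2.0) / (lam + 1.0))

    res = minimize_scalar(
        lambda mu: np.sum((x - mu) ** 2) + lam * mu**2,
        bracket=(float(x.min()) - 1.0, float(x.max()) + 1.0),
    )
    m0 = float(res.x)
    su = 1.0 / math.sqrt(n + lam)

    def log_integrand(u: np.ndarray, lt: np.ndarray) -> np.ndarray:
        U, LT = u[None, :], lt[:, None]
        tau = np.exp(LT)
        mu = m0 + U / np.sqrt(tau)
        sq = np.zeros_like(mu)
        for xi in x:
            sq += (xi - mu) ** 2
        loglik = 0.5 * n * LT - 0.5 * n * math.log(2 * math.pi) - 0.5 * tau * sq
        logprior_mu = (
            0.5 * (math.log(lam) + LT)
            - 0.5 * math.log(2 * math.pi)
            - 0.5 * lam * tau * mu**2
        )
        logprior_tau = (
            alpha * math.log(beta) - gammaln(alpha) + (alpha - 1.0) * LT - beta * tau
        )
        # Jacobians: dtau = tau d(lt) contributes +LT; dmu = du/sqrt(tau), -LT/2
        return loglik + logprior_mu + logprior_tau + 0.5 * LT

    lt_scan = np.linspace(-30.0, 15.0, 2001)
    ridge = log_integrand(np.array([0.0]), lt_scan)[:, 0]
    lt_star = float(lt_scan[np.argmax(ridge)])
    a_post = alpha + n / 2.0
    lt_lo, lt_hi = lt_star - 45.0 / a_post - 6.0, lt_star + 8.0

    gu, wu = np.polynomial.legendre.leggauss(nodes)
    gl, wl = np.polynomial.legendre.leggauss(nodes)
    ua, ub = -16.0 * su, 16.0 * su
    U = 0.5 * (ub - ua) * gu + 0.5 * (ub + ua)
    LT = 0.5 * (lt_hi - lt_lo) * gl + 0.5 * (lt_hi + lt_lo)
    G = log_integrand(U, LT)
    shift = float(G.max())
    val = np.einsum("i,j,ij->", wl, wu, np.exp(G - shift))
    val *= 0.25 * (ub - ua) * (lt_hi - lt_lo)
    return shift + math.log(val)


def ng_log_marginal_chain(x, alpha: float, lam: float) -> float:
    """Normal-Gamma log marginal as a product of Student-t predictives.

    Processes the data one point at a time with conjugate updating; each
    one-step-ahead predictive is a Student-t density. Independent of the
    closed-form batch expression the implementation uses.
    """
    beta = max(1.0, lam * (alpha - 2.0) / (lam + 1.0))
    mu = 0.0
    total = 0.0
    for xi in np.asarray(x, dtype=float):
        df = 2.0 * alpha
        scale = math.sqrt(beta * (lam + 1.0) / (alpha * lam))
        total += float(student_t.logpdf(xi, df=df, loc=mu, scale=scale))
        beta = beta + lam * (xi - mu) ** 2 / (2.0 * (lam + 1.0))
        mu = (lam * mu + xi) / (lam + 1.0)
        lam += 1.0
        alpha += 0.5
    return total


def emd_lp(centers_p, weights_p, centers_q, weights_q) -> float:
    """EMD via the transportation linear program (scipy.optimize.linprog)."""
    cp = np.asarray(centers_p, dtype=float)
    cq = np.asarray(centers_q, dtype=float)
    wp = np.asarray(weights_p, dtype=float)
    wq = np.asarray(weights_q, dtype=float)
    m, n = cp.size, cq.size
    cost = np.abs(cp[:, None] - cq[None, :]).ravel()
    A_eq = []
    b_eq = []
    for i in range(m):
        row = np.zeros(m * n)
        row[i * n : (i + 1) * n] = 1.0
        A_eq.append(row)
        b_eq.append(wp[i])
    for j in range(n):
        row = np.zeros(m * n)
        row[j::n] = 1.0
        A_eq.append(row)
        b_eq.append(wq[j])
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
    assert res.success, res.message
    total_flow = float(np.sum(res.x))
    return float(res.fun) / total_flow


def emd_cdf_closed_form(weights_p, weights_q, cell_width: float) -> float:
    """1-D EMD on a shared equal-width grid: area between the CDFs."""
    cdf_p = np.cumsum(np.asarray(weights_p, dtype=float))
    cdf_q = np.cumsum(np.asarray(weights_q, dtype=float))
    return float(np.abs(cdf_p - cdf_q).sum() * cell_width)
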