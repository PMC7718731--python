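"""Compiled inner loops of the Gibbs samplers.

The single-site marker sweep is sequential over loci and traits, so it is
written as an explicit loop and jit-compiled.  All random numbers it
consumes are pre-generated by the caller from one seeded Generator, which
keeps chains bit-reproducible and independent of the compilation path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def marker_sweep(
    M,  # (n, p) genotype covariates, float64, C-order
    m2,  # (p,) column sums of squares of M
    e,  # (n, t) residuals  (working response - mu - M @ alpha), updated in place
    f,  # (n, t) e @ omega, updated in place
    beta,  # (p, t) marker effects, updated in place
    delta,  # (p, t) inclusion indicators in {0., 1.}, updated in place
    omega,  # (t, t) inverse of R
    cond_coef,  # (t, t) rows: coefficients of the conditional prior mean of
    # beta_jk given beta_j,-k under N(0, G); diagonal entries are zero
    cond_var,  # (t,) conditional prior variances
    log_pi,  # (2**t,) log mixture probabilities; label index = sum_k delta_k << k
    u,  # (p, t) uniforms for the delta draws
    z,  # (p, t) standard normals for the beta draws
):
    """One full single-site sweep over all loci and traits.

    For each (locus j, trait k) the inclusion indicator is drawn from its
    Bernoulli full conditional with beta_jk integrated out under its
    conditional prior, then beta_jk is drawn from its normal full
    conditional (included) or the conditional prior (excluded).
    """
    n, t = e.shape
    p = M.shape[1]
    for j in range(p):
        for k in range(t):
            lab0 = 0
            for l in range(t):
                if l != k and delta[j, l] != 0.0:
                    lab0 += 1 << l
            lab1 = lab0 + (1 << k)
            prior_log_odds = log_pi[lab1] - log_pi[lab0]

            v0 = cond_var[k]
            m0 = 0.0
            for l in range(t):
                m0 += cond_coef[k, l] * beta[j, l]

            a_old = delta[j, k] * beta[j, k]
            rhs = a_old * omega[k, k] * m2[j]
            for i in range(n):
                rhs += M[i, j] * f[i, k]
            q = m2[j] * omega[k, k]
            prec = q + 1.0 / v0
            b = (rhs + m0 / v0) / prec
            log_bf = 0.5 * (-np.log(v0 * prec) + b * b * prec - m0 * m0 / v0)
            logit = prior_log_odds + log_bf
            if logit > 35.0:
                p1 = 1.0
            elif logit < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-logit))

            if u[j, k] < p1:
                d_new = 1.0
                b_new = b + z[j, k] / np.sqrt(prec)
            else:
                d_new = 0.0
                b_new = m0 + z[j, k] * np.sqrt(v0)
            delta[j, k] = d_new
            beta[j, k] = b_new
            diff = d_new * b_new - a_old
            if diff != 0.0:
                for i in range(n):
                    mij = M[i, j]
                    if mij != 0.0:
                        e[i, k] -= mij * diff
                        for l in range(t):
                            f[i, l] -= mij * diff * omega[k, l]


@njit(cache=True)
def marker_sweep_mtm(
    MTM,  # (p, p) genotype cross-products M'M
    m2,  # (p,) diagonal of MTM
    RHS,  # (p, t) M' (e @ omega) for the residual e at sweep start; kept in
    # sync with the sequential effect updates, in place
    beta,  # (p, t) updated in place
    delta,  # (p, t) updated in place
    omega,  # (t, t) inverse of R
    cond_coef,
    cond_var,
    log_pi,
    u,
    z,
):
    """Marker-space variant of :func:`marker_sweep`.

    Identical draws (same pre-generated u, z) but O(p t) per effect
    update instead of O(n) per visit, which wins when p is moderate and
    the inclusion rate is low.  Requires the dense p x p cross-product.
    """
    p, t = beta.shape
    for j in range(p):
        for k in range(t):
            lab0 = 0
            for l in range(t):
                if l != k and delta[j, l] != 0.0:
                    lab0 += 1 << l
            lab1 = lab0 + (1 << k)
            prior_log_odds = log_pi[lab1] - log_pi[lab0]

            v0 = cond_var[k]
            m0 = 0.0
            for l in range(t):
                m0 += cond_coef[k, l] * beta[j, l]

            a_old = delta[j, k] * beta[j, k]
            rhs = RHS[j, k] + a_old * omega[k, k] * m2[j]
            q = m2[j] * omega[k, k]
            prec = q + 1.0 / v0
            b = (rhs + m0 / v0) / prec
            log_bf = 0.5 * (-np.log(v0 * prec) + b * b * prec - m0 * m0 / v0)
            logit = prior_log_odds + log_bf
            if logit > 35.0:
                p1 = 1.0
            elif logit < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-logit))

            if u[j, k] < p1:
                d_new = 1.0
                b_new = b + z[j, k] / np.sqrt(prec)
            else:
                d_new = 0.0
                b_new = m0 + z[j, k] * np.sqrt(v0)
            delta[j, k] = d_new
            beta[j, k] = b_new
            diff = d_new * b_new - a_old
            if diff != 0.0:
                for jj in range(p):
                    mm = MTM[jj, j] * diff
                    for l in range(t):
                        RHS[jj, l] -= mm * omega[k, l]


def safe_log(pi: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(pi, _TINY))
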