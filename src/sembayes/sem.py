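"""SEM-BayesC-pi: the structural-equation Gibbs sampler.

The recursive system among traits is

    y_i = Lambda y_i + mu + sum_j m_ij D_j beta_j + e_i

which, with Lambda* = I - Lambda, becomes a multi-trait regression on the
working response Lambda* y_i.  Identifiability of the structural
coefficients requires a diagonal residual covariance.  Because the
system is recursive, det(Lambda*) = 1 and the Jacobian term drops out of
the likelihood, so lambda has an exact multivariate-normal full
conditional:

    V   = (sum_i Y_i' R^-1 Y_i + I / tau^2)^-1
    hat = V (sum_i Y_i' R^-1 w_i + 1 lambda0 / tau^2)

with w_i = y_i - mu - sum_j m_ij alpha_j and Y_i the sparse matrix for
which Lambda* y_i = y_i - Y_i lambda.
"""

from __future__ import annotations

import numpy as np

from .data import CausalStructure, ChainConfig, GenotypeData, PhenotypeData, PriorConfig

__all__ = [
    "build_lambda_star",
    "build_Yi",
    "sample_lambda",
    "sample_R_diag",
    "run_sem_chain",
]


def build_lambda_star(lam: CausalStructure) -> np.ndarray:
    """I - Lambda.  Its determinant is 1 for any recursive structure."""
    return lam.lambda_star()


def build_Yi(y_i: np.ndarray, support: list[tuple[int, int]]) -> np.ndarray:
    """The t x s matrix with Lambda* y_i = y_i - Y_i lambda.

    Column c of Y_i, for support element (k, l), has y_i[l] in row k and
    zeros elsewhere.
    """
    t = len(y_i)
    Y = np.zeros((t, len(support)))
    for c, (k, l) in enumerate(support):
        Y[k, c] = y_i[l]
    return Y


def _lambda_moments(
    y: np.ndarray,
    w: np.ndarray,
    support: list[tuple[int, int]],
    omega: np.ndarray,
    tau2: float,
    lambda0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior covariance V and mean hat of the lambda full conditional."""
    s = len(support)
    A = np.empty((s, s))
    b = np.empty(s)
    wo = w @ omega
    for c, (k, l) in enumerate(support):
        b[c] = y[:, l] @ wo[:, k]
        for c2, (k2, l2) in enumerate(support):
            A[c, c2] = omega[k, k2] * (y[:, l] @ y[:, l2])
    V = np.linalg.inv(A + np.eye(s) / tau2)
    lam_hat = V @ (b + lambda0 / tau2 * np.ones(s))
    return lam_hat, V


def sample_lambda(
    y: np.ndarray,
    w: np.ndarray,
    support: list[tuple[int, int]],
    R: np.ndarray,
    priors: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw lambda ~ N(hat, V) from its full conditional.

    ``w`` are the residuals y_i - mu - sum_j m_ij alpha_j of the
    *untransformed* phenotypes.
    """
    if not support:
        return np.empty(0)
    omega = np.linalg.inv(R)
    lam_hat, V = _lambda_moments(y, w, support, omega, priors.tau2, priors.lambda0)
    return lam_hat + np.linalg.cholesky(V) @ rng.standard_normal(len(support))


def sample_R_diag(state, resid: np.ndarray, priors: PriorConfig, rng: np.random.Generator) -> np.ndarray:
    """Scaled inverse chi-square update of each residual variance.

    R_kk ~ (s_e,k nu_e + sum_i e_ik^2) / chisq(nu_e + n).
    """
    n, t = resid.shape
    scale = priors.s_e_diag * priors.nu_e + np.einsum("ik,ik->k", resid, resid)
    draws = scale / rng.chisquare(priors.nu_e + n, size=t)
    return np.diag(draws)


def _lambda_step(state, y, e, support, lam_vals, priors, rng):
    """Gibbs step for lambda followed by the working-response refresh.

    ``e`` is the current residual of the transformed system,
    Lambda* y - mu - M alpha, so w = e + Lambda y = e + Y lambda.
    """
    from .bayescpi import _y_contrib

    w = e + _y_contrib(y, support, lam_vals)
    lam_new = sample_lambda(y, w, support, state.R, priors, rng)
    for c, (k, l) in enumerate(support):
        state.lam.lam[k, l] = lam_new[c]
    ystar = y - _y_contrib(y, support, lam_new)
    return lam_new, ystar


def run_sem_chain(
    y: PhenotypeData | np.ndarray,
    g: GenotypeData | np.ndarray,
    structure: CausalStructure,
    priors: PriorConfig,
    chain: ChainConfig,
    **kwargs,
):
    """Fit SEM-BayesC-pi given a known (or discovered) causal support.

    ``structure`` supplies the support pattern of Lambda; its numeric
    values are sampled.  Residual covariance is constrained diagonal.
    Per sweep the update order is mu -> marker effects -> G -> R ->
    Pi -> lambda, with the working response refreshed after the lambda
    draw.
    """
    from .bayescpi import _run_chain

    ymat = y.matrix if isinstance(y, PhenotypeData) else np.asarray(y, dtype=np.float64)
    M = g.matrix if isinstance(g, GenotypeData) else np.asarray(g, dtype=np.float64)
    if ymat.shape[0] != M.shape[0]:
        raise ValueError("phenotypes and genotypes have different numbers of individuals")
    # fresh copy so the caller's structure is not mutated during sampling
    struct = CausalStructure(structure.lam.copy(), structure.trait_names)
    samples = _run_chain(ymat, M, priors, chain, structure=struct, diagonal_R=True, **kwargs)
    if isinstance(y, PhenotypeData):
        samples.trait_names = y.trait_names
    return samples
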