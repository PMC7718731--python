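"""SNP-effect decomposition and genomic-window association inference.

A locus's direct effect on the traits is its sampled alpha_j; the
indirect effect transmitted through intermediate traits is
sum_{rho=1}^{t-1} Lambda^rho alpha_j; their sum, (I - Lambda)^-1 alpha_j,
is the overall effect.  Decomposition uses the *joint* posterior sample
of Lambda and alpha at each retained iteration.

Window inference: for non-overlapping windows of consecutive markers
(100 by default, never spanning chromosome boundaries), the genetic
value attributed to window w is a_w = M_w alpha_w per effect type; its
population variance over individuals, divided by the total genetic
variance (from overall effects of all markers), gives q_w.  The window
posterior probability of association WPPA is the proportion of MCMC
samples with q_w strictly exceeding T = 1/N, N the number of windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayescpi import ChainSamples
from .data import CausalStructure, GenotypeData

logger = logging.getLogger(__name__)

__all__ = [
    "EffectDecomposition",
    "WindowTable",
    "decompose_effects",
    "define_windows",
    "window_variance_proportions",
    "compute_window_q",
    "wppa",
    "significant_windows",
    "pleiotropy_proportions",
]

EFFECT_TYPES = ("direct", "indirect", "overall")


@dataclass
class EffectDecomposition:
    """Per-sample direct/indirect/overall marker-effect arrays, (S, p, t)."""

    direct: np.ndarray
    indirect: np.ndarray
    overall: np.ndarray


@dataclass
class WindowTable:
    """Window definitions plus q_w samples and WPPA per effect type.

    ``frame`` has one row per window with columns window_id, chrom,
    start, stop (half-open span over map order) and n_snps.  ``q`` maps
    effect type to an (S, W, t) array of per-sample variance
    proportions; ``wppa`` maps effect type to a (W, t) array.
    """

    frame: pd.DataFrame
    threshold: float | None = None
    q: dict[str, np.ndarray] = field(default_factory=dict)
    wppa: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.frame)


def _power_sum(lam: np.ndarray, lo: int) -> np.ndarray:
    """sum_{rho=lo}^{t-1} Lambda^rho (equals (I-Lambda)^-1 for lo=0)."""
    t = lam.shape[0]
    acc = np.zeros((t, t))
    power = np.eye(t)
    for rho in range(t):
        if rho >= lo:
            acc += power
        power = power @ lam
    return acc


def decompose_effects(
    alpha_sample: np.ndarray, lam_sample: CausalStructure | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split one sample's p x t effects into direct, indirect, overall.

    direct = alpha; indirect_j = sum_{rho>=1} Lambda^rho alpha_j;
    overall_j = (I - Lambda)^-1 alpha_j = direct_j + indirect_j.
    """
    lam = lam_sample.lam if isinstance(lam_sample, CausalStructure) else np.asarray(lam_sample)
    direct = np.asarray(alpha_sample, dtype=np.float64)
    indirect = direct @ _power_sum(lam, 1).T
    return direct, indirect, direct + indirect


def decompose_chain(chain: ChainSamples) -> EffectDecomposition:
    """Decompose every retained sample with its own Lambda draw."""
    lams = chain.lam_matrices()
    direct = chain.alpha
    indirect = np.empty_like(direct)
    for s in range(chain.n_samples):
        indirect[s] = direct[s] @ _power_sum(lams[s], 1).T
    return EffectDecomposition(direct=direct, indirect=indirect, overall=direct + indirect)


def define_windows(marker_map: pd.DataFrame, window_size: int = 100) -> WindowTable:
    """Consecutive non-overlapping windows of at most ``window_size`` SNPs.

    Windows never span chromosome boundaries; the last window on each
    chromosome may be smaller.  ``marker_map`` must be in map order with
    a ``chrom`` column.
    """
    if window_size < 1:
        raise ValueError("window_size must be positive")
    chrom = np.asarray(marker_map["chrom"])
    rows = []
    wid = 0
    start = 0
    p = len(chrom)
    for i in range(p):
        boundary = i + 1 == p or chrom[i + 1] != chrom[i]
        if (i + 1 - start) == window_size or boundary:
            rows.append(
                {"window_id": wid, "chrom": chrom[start], "start": start, "stop": i + 1,
                 "n_snps": i + 1 - start}
            )
            wid += 1
            start = i + 1
    frame = pd.DataFrame(rows)
    logger.info("defined %d windows over %d markers", len(frame), p)
    return WindowTable(frame=frame, threshold=1.0 / len(frame) if len(frame) else None)


def window_variance_proportions(
    effects: tuple[np.ndarray, np.ndarray, np.ndarray],
    g: GenotypeData | np.ndarray,
    windows: WindowTable,
) -> dict[str, np.ndarray]:
    """q_w for one retained sample: window share of total genetic variance.

    Variances divide by n (population form).  The denominator uses the
    overall effects of all markers.  q is not clamped: it can exceed 1
    when a window's genetic values anti-correlate with the remainder.
    """
    M = g.matrix if isinstance(g, GenotypeData) else np.asarray(g, dtype=np.float64)
    direct, indirect, overall = effects
    a_total = M @ overall
    sigma_a = a_total.var(axis=0)
    out = {}
    zero_total = sigma_a <= 0
    if zero_total.any():
        logger.warning("total genetic variance is zero for %d trait(s); q set to 0", zero_total.sum())
    for name, eff in zip(EFFECT_TYPES, (direct, indirect, overall)):
        q = np.zeros((windows.n_windows, eff.shape[1]))
        for w, row in enumerate(windows.frame.itertuples()):
            a_w = M[:, row.start : row.stop] @ eff[row.start : row.stop]
            var_w = a_w.var(axis=0)
            q[w] = np.divide(var_w, sigma_a, out=np.zeros_like(var_w), where=~zero_total)
        out[name] = q
    return out


def compute_window_q(
    chain: ChainSamples, g: GenotypeData | np.ndarray, windows: WindowTable
) -> WindowTable:
    """Fill ``windows.q`` with per-sample q_w arrays for all effect types."""
    M = g.matrix if isinstance(g, GenotypeData) else np.asarray(g, dtype=np.float64)
    dec = decompose_chain(chain)
    S, W, t = chain.n_samples, windows.n_windows, chain.t
    spans = [(row.start, row.stop) for row in windows.frame.itertuples()]
    a_total = np.tensordot(M, dec.overall, axes=(1, 1))  # (n, S, t)
    sigma_a = a_total.var(axis=0)  # (S, t)
    ok = sigma_a > 0
    if not ok.all():
        logger.warning("zero total genetic variance in %d sample-trait cells; q set to 0",
                       int((~ok).sum()))
    for name, eff in (("direct", dec.direct), ("indirect", dec.indirect), ("overall", dec.overall)):
        q = np.zeros((S, W, t))
        for w, (lo, hi) in enumerate(spans):
            var_w = np.tensordot(M[:, lo:hi], eff[:, lo:hi, :], axes=(1, 1)).var(axis=0)
            np.divide(var_w, sigma_a, out=q[:, w, :], where=ok)
        windows.q[name] = q
    return windows


def wppa(q_samples: np.ndarray, T: float) -> float | np.ndarray:
    """Proportion of MCMC samples of q_w strictly exceeding T."""
    q_samples = np.asarray(q_samples)
    if q_samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    return (q_samples > T).mean(axis=0)


def compute_wppa(windows: WindowTable, T: float | None = None) -> WindowTable:
    """WPPA per window, effect type and trait, at threshold T = 1/N."""
    if T is None:
        T = 1.0 / windows.n_windows
    windows.threshold = T
    for name, q in windows.q.items():
        windows.wppa[name] = wppa(q, T)
    return windows


def significant_windows(
    windows: WindowTable, wppa_threshold: float = 0.8
) -> dict[str, np.ndarray]:
    """Boolean (W, t) masks of windows with WPPA >= threshold.

    A WPPA cutoff of alpha bounds the proportion of false positives
    among declared windows below 1 - alpha.
    """
    if not windows.wppa:
        raise ValueError("WPPA has not been computed")
    return {name: w >= wppa_threshold for name, w in windows.wppa.items()}


def windows_frame(windows: WindowTable) -> pd.DataFrame:
    """Long-format summary: one row per (window, effect type, trait)."""
    rows = []
    for name, w in windows.wppa.items():
        qmean = windows.q[name].mean(axis=0)
        for widx, row in enumerate(windows.frame.itertuples()):
            for k in range(w.shape[1]):
                rows.append(
                    {
                        "window_id": row.window_id,
                        "chrom": row.chrom,
                        "start": row.start,
                        "stop": row.stop,
                        "effect_type": name,
                        "trait": k,
                        "q_mean": qmean[widx, k],
                        "wppa": w[widx, k],
                    }
                )
    return pd.DataFrame(rows)


def pleiotropy_proportions(chain: ChainSamples) -> dict[str, np.ndarray]:
    """Proportion of markers affecting each trait combination.

    ``direct`` is the posterior mean of Pi per label.  ``overall``
    counts, per sample and locus, the traits reached by any included
    direct effect through the sampled Lambda paths (a locus with a
    direct effect only on an upstream trait still has an overall effect
    on its causal descendants); label frequencies are averaged over
    samples.  Labels are indexed as in :class:`MixtureLabels`.
    """
    t = chain.t
    nlab = 2**t
    direct = chain.pi.mean(axis=0)

    lams = chain.lam_matrices()
    weights = (1 << np.arange(t)).astype(np.int64)
    p = chain.alpha.shape[1]
    freq = np.zeros(nlab)
    for s in range(chain.n_samples):
        reach = (np.abs(_power_sum(lams[s], 0)) > 1e-12).astype(np.float64)  # reach[k,l]: l reaches k
        overall_ind = (chain.delta[s].astype(np.float64) @ reach.T) > 0
        idx = overall_ind.astype(np.int64) @ weights
        freq += np.bincount(idx, minlength=nlab) / p
    overall = freq / chain.n_samples
    return {"direct": direct, "overall": overall}
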