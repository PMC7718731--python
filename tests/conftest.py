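"""Shared fixtures, including the heavy parameter-recovery replicates."""

from __future__ import annotations

import numpy as np
import pytest

from sembayes.data import CausalStructure, ChainConfig, default_priors
from sembayes.evaluation import RocInput, pauc5, rescale_pauc5
from sembayes.sem import run_sem_chain
from sembayes.simulate import SimConfig, simulate_dataset, truth_windows
from sembayes.windows import compute_window_q, compute_wppa, define_windows


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic small dataset with its truth record."""
    cfg = SimConfig(n=120, p=200, n_qtl=10, gamma_shape=1.48, seed=7)
    g, y, truth = simulate_dataset(cfg)
    return cfg, g, y, truth


def _one_recovery_replicate(rep: int) -> dict:
    """Simulate, fit SEM-BayesC-pi, and score one replicate.

    Study conditions: n=500, p=1000, nQTL=30, gamma shape 0.18,
    lambda=1, h2=0.5; 20,000 sweeps with 5,000 burn-in, thinned to
    1,500 retained samples.  Windows of 10 SNPs keep the window:QTL
    ratio comparable to a genome-scale panel scored with 100-SNP
    windows.
    """
    cfg = SimConfig(n=500, p=1000, n_qtl=30, gamma_shape=0.18, seed=1000 + rep)
    g, y, truth = simulate_dataset(cfg)
    support = CausalStructure(np.array([[0.0, 0.0], [1.0, 0.0]]))
    chain = run_sem_chain(
        y, g, support, default_priors(y, g),
        ChainConfig(n_iter=20_000, burn_in=5_000, thin=10, seed=rep),
    )
    lam = chain.lam[:, 0]
    lo, hi = np.quantile(lam, [0.05, 0.95])

    wt = define_windows(g.map_frame(), window_size=10)
    compute_window_q(chain, g, wt)
    compute_wppa(wt)
    labels = truth_windows(truth, wt)["overall"][:, 1]
    scores = wt.wppa["overall"][:, 1]
    pauc = rescale_pauc5(pauc5(RocInput(scores, labels)))
    return {
        "lam_mean": float(lam.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "covers": bool(lo <= 1.0 <= hi),
        "pauc_overall_t2": float(pauc),
    }


@pytest.fixture(scope="session")
def recovery_replicates():
    """Twenty seeded replicates of the scaled-down benchmark experiment."""
    return [_one_recovery_replicate(rep) for rep in range(20)]
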