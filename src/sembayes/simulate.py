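"""Synthetic two-trait GWAS data with a known causal chain.

The generator reproduces the statistical structure of the benchmarking
design: binomial genotypes at uniform allele frequencies, QTL effect
magnitudes from a unit-scale gamma distribution (shape 0.18, 1.48 or
3.0), QTL counts of 30, 90 or 300, and two QTL scenarios — scenario 1
gives a QTL direct effects on both traits, scenario 2 on trait 1 only,
half the QTL each.  Trait 1 causally affects trait 2 with structural
coefficient lambda = 1.0 and each trait has heritability 0.5 on its own
structural-equation scale.  Effect signs are randomised (+/- with equal
probability) so genetic values are not systematically directional.

The full truth record (QTL positions, per-trait direct effects, Lambda,
window-level association flags) supports ROC scoring of any window
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CausalStructure, GenotypeData, PhenotypeData
from .windows import WindowTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_qtl_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "truth_windows",
]


@dataclass
class SimConfig:
    """Simulation settings; defaults follow the benchmark design."""

    n: int = 500
    p: int = 1000
    n_qtl: int = 30
    gamma_shape: float = 0.18
    lambda_true: float = 1.0
    h2: float = 0.5
    scenario_split: float = 0.5
    freq_range: tuple[float, float] = (0.05, 0.5)
    ld_mix: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_qtl > self.p:
            raise ValueError("n_qtl cannot exceed p")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("freq_range must lie inside (0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    qtl_positions: np.ndarray  # (n_qtl,) marker indices
    scenario: np.ndarray  # (n_qtl,) labels in {1, 2}
    direct_effects: np.ndarray  # (p, t) true direct effects (zero off QTL)
    lam: CausalStructure

    @property
    def t(self) -> int:
        return self.direct_effects.shape[1]


def simulate_genotypes(
    n: int,
    p: int,
    freq_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    ld_mix: float = 0.0,
) -> GenotypeData:
    """Binomial(2, f) genotypes with f ~ Uniform(freq_range) per marker.

    ``ld_mix`` in [0, 1) introduces first-order correlation between
    adjacent markers by copying each individual's previous-marker
    genotype with that probability, a crude stand-in for LD.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(*freq_range, size=p)
    mat = rng.binomial(2, f, size=(n, p)).astype(np.float64)
    if ld_mix > 0:
        copy = rng.random((n, p)) < ld_mix
        for j in range(1, p):
            mat[copy[:, j], j] = mat[copy[:, j], j - 1]
    ids = np.array([f"ind{i}" for i in range(n)], dtype=object)
    markers = np.array([f"m{j:05d}" for j in range(p)], dtype=object)
    return GenotypeData(mat, markers, np.ones(p, dtype=np.int64), np.arange(p), ids)


def simulate_qtl_effects(config: SimConfig, seed: int | None = None) -> SimTruth:
    """Draw QTL positions, scenarios and direct effects.

    Magnitudes are Gamma(shape, scale=1); signs are +/-1 with equal
    probability.  QTL positions are sampled uniformly without
    replacement; half follow scenario 1 (direct effects on both traits)
    and half scenario 2 (trait 1 only), the first ceil(n_qtl/2) taking
    scenario 1 when n_qtl is odd.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pos = np.sort(rng.choice(config.p, size=config.n_qtl, replace=False))
    n1 = int(np.ceil(config.n_qtl * config.scenario_split))
    scenario = np.full(config.n_qtl, 2, dtype=np.int64)
    which1 = rng.choice(config.n_qtl, size=n1, replace=False)
    scenario[which1] = 1

    t = 2
    effects = np.zeros((config.p, t))
    mags = rng.gamma(config.gamma_shape, 1.0, size=(config.n_qtl, t))
    signs = rng.choice((-1.0, 1.0), size=(config.n_qtl, t))
    effects[pos, 0] = mags[:, 0] * signs[:, 0]
    effects[pos, 1] = np.where(scenario == 1, mags[:, 1] * signs[:, 1], 0.0)

    lam = np.zeros((t, t))
    lam[1, 0] = config.lambda_true
    return SimTruth(
        qtl_positions=pos,
        scenario=scenario,
        direct_effects=effects,
        lam=CausalStructure(lam, np.array(["trait1", "trait2"], dtype=object)),
    )


def simulate_phenotypes(
    g: GenotypeData, truth: SimTruth, config: SimConfig, seed: int | None = None
) -> PhenotypeData:
    """Generate phenotypes through the recursive system.

    Per trait k (in topological order): u_k = M alpha_k^direct, residual
    variance chosen so var(u_k) / (var(u_k) + var(e_k)) = h2 on that
    equation's scale, and y_k = sum_l lambda_kl y_l + u_k + e_k.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    M = g.matrix
    n = M.shape[0]
    t = truth.t
    u = M @ truth.direct_effects
    y = np.zeros((n, t))
    lam = truth.lam.lam
    for k in truth.lam.topological_order():
        var_u = u[:, k].var()
        if var_u <= 0:
            # purely downstream trait (e.g. scenario-2-only QTL): scale the
            # noise off the inherited causal signal instead
            var_u = (lam[k] @ y.T).var()
        if var_u <= 0:
            raise ValueError(
                f"trait {k} has neither direct genetic variance nor causal "
                "input; use a scenario mix that gives every trait a signal"
            )
        sd_e = np.sqrt(var_u * (1.0 - config.h2) / config.h2)
        e = rng.normal(0.0, sd_e, size=n)
        y[:, k] = lam[k] @ y.T + u[:, k] + e
    ids = g.individual_ids
    names = np.array([f"trait{k + 1}" for k in range(t)], dtype=object)
    return PhenotypeData(y, names, ids)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeData, PhenotypeData, SimTruth]:
    """Genotypes, phenotypes and truth from one seed (deterministic)."""
    g = simulate_genotypes(config.n, config.p, config.freq_range, seed=config.seed, ld_mix=config.ld_mix)
    truth = simulate_qtl_effects(config, seed=config.seed + 10_000)
    y = simulate_phenotypes(g, truth, config, seed=config.seed + 20_000)
    return g, y, truth


def truth_windows(truth: SimTruth, windows: WindowTable) -> dict[str, np.ndarray]:
    """Per-window binary truth flags per effect type and trait.

    A window is truly associated with trait k through: direct effects
    iff it contains a QTL with nonzero direct effect on k; indirect
    effects iff it contains a QTL with nonzero direct effect on a causal
    ancestor of k; overall effects iff either holds.
    """
    t = truth.t
    W = windows.n_windows
    direct = np.zeros((W, t), dtype=bool)
    indirect = np.zeros((W, t), dtype=bool)
    anc = {k: truth.lam.ancestors(k) for k in range(t)}
    for w, row in enumerate(windows.frame.itertuples()):
        eff = truth.direct_effects[row.start : row.stop]
        nonzero = np.any(eff != 0, axis=0)  # per-trait
        for k in range(t):
            direct[w, k] = bool(nonzero[k])
            indirect[w, k] = bool(any(nonzero[a] for a in anc[k]))
    return {"direct": direct, "indirect": indirect, "overall": direct | indirect}
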