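# sembayes

Multi-trait Bayesian variable-selection GWAS with a structural equation
model among traits (SEM-BayesCΠ).

## Who this is for

Quantitative geneticists running genome-wide association studies on
several correlated traits who want more than a per-trait scan: when
traits affect each other causally (say plant height driving flowering
time), a marker's effect on a downstream trait mixes a *direct*
biological effect with an *indirect* one transmitted through the
upstream trait.  This package jointly estimates the marker effects, the
causal structure among traits, and the decomposition of every marker
effect into direct, indirect and overall components — with full
posterior uncertainty for each.

## The model

For individual *i* with *t* traits and *p* loci (genotypes coded
0/1/2),

```
y_i = Λ y_i + μ + Σ_j m_ij D_j β_j + e_i
```

where Λ is a t×t matrix of structural coefficients whose nonzero
support is an acyclic graph (entry Λ[k,l] is the effect of a one-unit
change in trait *l* on trait *k*), β_j ~ N(0, G) are marker effects,
D_j = diag(δ_j) holds per-trait inclusion indicators with a 2^t-label
mixture prior governed by Π (uniform Dirichlet prior), and the residual
covariance is diagonal for identifiability.  Since the system is
recursive, det(I − Λ) = 1 and the structural coefficients have an exact
multivariate-normal Gibbs update.  With Λ ≡ 0 and a full residual
covariance this reduces to the exchangeable multi-trait BayesCΠ model,
whose posterior residual covariances drive causal-structure discovery
(residual partial correlations → 0.9 HPD decisions → IC algorithm →
Markov equivalence class of structures).

Per retained MCMC sample, effects decompose as direct = α_j, indirect =
Σ_{ρ≥1} Λ^ρ α_j, overall = (I−Λ)^{-1} α_j.  Association is tested per
genomic window: q_w is the window's share of total genetic variance and
WPPA is the posterior probability that q_w exceeds T = 1/N (N windows);
WPPA ≥ 0.8 declares a window significant, bounding the proportion of
false positives below 0.2.  A simulation harness and partial-AUC
(pAUC5) scoring complete the benchmarking loop.

## Worked example

```python
import numpy as np
from sembayes import (SimConfig, simulate_dataset, truth_windows,
                      CausalStructure, ChainConfig, default_priors,
                      run_sem_chain, define_windows, compute_window_q,
                      compute_wppa, significant_windows, evaluate_run)

cfg = SimConfig(n=500, p=1000, n_qtl=30, gamma_shape=0.18, seed=11)
g, y, truth = simulate_dataset(cfg)          # trait1 -> trait2, lambda = 1
support = CausalStructure(np.array([[0., 0.], [1., 0.]]))
chain = run_sem_chain(y, g, support, default_priors(y, g),
                      ChainConfig(n_iter=10_000, burn_in=2_000, thin=8, seed=1))
lam = chain.lam[:, 0]
print(f"lambda posterior mean {lam.mean():.3f}, sd {lam.std():.3f}")

wt = define_windows(g.map_frame(), window_size=10)
compute_window_q(chain, g, wt)
compute_wppa(wt)                              # T = 1/N = 0.01
sig = significant_windows(wt, 0.8)
print(np.flatnonzero(sig["overall"][:, 1]))   # significant windows, trait 2
print(evaluate_run(wt, truth_windows(truth, wt)))
```

prints

```
lambda posterior mean 0.996, sd 0.046
[ 9 15 19 35 66]
 trait effect_type  rescaled_pauc5
     0      direct        8.878096
     1      direct        5.352941
     0    indirect             NaN
     1    indirect        8.878096
     0     overall        8.878096
     1     overall       10.257407
```

The structural coefficient is recovered near its simulated value 1.0;
the five windows declared at WPPA ≥ 0.8 for trait 2's overall effects
all contain true QTL; rescaled pAUC5 values well above 1 mean the WPPA
ranking beats a random classifier inside the 5% false-positive strip
(indirect effects on trait 1 are structurally impossible here, hence
NaN).

The same flow is available from the shell:

```
sembayes simulate --seed 11 --out-dir run/
sembayes fit-sem --geno run/genotypes.csv --pheno run/phenotypes.csv \
    --structure run/true_structure.csv --seed 1 --out run/chain.npz
sembayes windows --chain run/chain.npz --geno run/genotypes.csv \
    --map run/map.csv --out run/windows.csv
sembayes pipeline --config config.yaml --out-dir run/   # end to end
```

plus `fit-mt` (exchangeable model) and `discover` (IC structure search
from posterior residual covariances).

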