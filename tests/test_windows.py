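"""Effect decomposition, window variance shares, WPPA and pleiotropy."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sembayes.bayescpi import ChainSamples
from sembayes.data import CausalStructure
from sembayes.windows import (
    WindowTable,
    _power_sum,
    compute_window_q,
    compute_wppa,
    decompose_chain,
    decompose_effects,
    define_windows,
    pleiotropy_proportions,
    significant_windows,
    window_variance_proportions,
    wppa,
)

RNG = np.random.default_rng


def _chain3():
    lam = np.zeros((3, 3))
    lam[1, 0], lam[2, 0], lam[2, 1] = 0.5, 0.2, 0.3
    return CausalStructure(lam)


def _map(p, chrom=None):
    chrom = np.ones(p, dtype=int) if chrom is None else np.asarray(chrom)
    return pd.DataFrame({"marker_id": [f"m{j}" for j in range(p)],
                         "chrom": chrom, "pos": np.arange(p)})


class TestDecomposition:
    def test_zero_lambda(self):
        alpha = RNG(0).normal(size=(5, 3))
        direct, indirect, overall = decompose_effects(alpha, CausalStructure(np.zeros((3, 3))))
        np.testing.assert_array_equal(indirect, 0)
        np.testing.assert_array_equal(overall, direct)

    def test_chain_pattern_worked_example(self):
        """alpha_j = (1,0,0): indirect = (0, .5, .2 + .5*.3); and the
        (I - Lambda)^-1 route gives the same overall effect."""
        alpha = np.array([[1.0, 0.0, 0.0]])
        direct, indirect, overall = decompose_effects(alpha, _chain3())
        np.testing.assert_allclose(indirect[0], [0.0, 0.5, 0.35])
        np.testing.assert_allclose(overall[0], [1.0, 0.5, 0.35])
        oracle = np.linalg.solve(np.eye(3) - _chain3().lam, alpha[0])
        np.testing.assert_allclose(overall[0], oracle)

    def test_chain_pattern_second_trait(self):
        alpha = np.array([[0.0, 1.0, 0.0]])
        _, indirect, overall = decompose_effects(alpha, _chain3())
        np.testing.assert_allclose(indirect[0], [0.0, 0.0, 0.3])
        np.testing.assert_allclose(overall[0], [0.0, 1.0, 0.3])

    @given(st.integers(2, 5), st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_power_sum_equals_inverse(self, t, rnd):
        """sum_{rho<t} Lambda^rho = (I - Lambda)^-1 for nilpotent Lambda."""
        rng = np.random.default_rng(rnd.getrandbits(32))
        lam = np.tril(rng.normal(0, 1, (t, t)), k=-1)
        perm = rng.permutation(t)
        lam = lam[np.ix_(perm, perm)]
        np.testing.assert_allclose(_power_sum(lam, 0), np.linalg.inv(np.eye(t) - lam), atol=1e-9)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_decomposition_identity(self, rnd):
        """overall - direct - indirect = 0 and (I-Lambda) overall = direct."""
        rng = np.random.default_rng(rnd.getrandbits(32))
        t = int(rng.integers(2, 5))
        lam = np.tril(rng.normal(0, 1, (t, t)), k=-1)
        s = CausalStructure(lam)
        alpha = rng.normal(size=(7, t))
        direct, indirect, overall = decompose_effects(alpha, s)
        np.testing.assert_allclose(overall - direct - indirect, 0, atol=1e-10)
        np.testing.assert_allclose(overall @ s.lambda_star().T, direct, atol=1e-10)

    def test_no_inbound_edge_means_no_indirect(self):
        """Source traits (no causal parent) have identically zero
        indirect effects."""
        alpha = RNG(1).normal(size=(20, 3))
        _, indirect, _ = decompose_effects(alpha, _chain3())
        np.testing.assert_array_equal(indirect[:, 0], 0.0)


class TestDefineWindows:
    def test_single_chromosome_trailing_block(self):
        wt = define_windows(_map(250), 100)
        assert list(wt.frame["n_snps"]) == [100, 100, 50]
        assert list(wt.frame["start"]) == [0, 100, 200]

    def test_chromosome_boundaries_respected(self):
        chrom = np.repeat([1, 2], 150)
        wt = define_windows(_map(300, chrom), 100)
        assert list(wt.frame["n_snps"]) == [100, 50, 100, 50]
        assert list(wt.frame["chrom"]) == [1, 1, 2, 2]

    def test_genome_scale_window_count(self):
        wt = define_windows(_map(33_519), 100)
        assert wt.n_windows == 336  # ceil(33519 / 100), single chromosome
        assert wt.threshold == pytest.approx(1 / 336)


class TestWindowVariance:
    def test_population_variance_formula(self):
        """var(a_w) = mean of squares minus squared mean, divide-by-n."""
        M = np.eye(3)
        eff = np.array([[1.0], [2.0], [3.0]])  # a_w = (1,2,3)
        wt = define_windows(_map(3), 3)
        q = window_variance_proportions((eff, np.zeros_like(eff), eff), M, wt)
        # single window: q = 1; the raw variance is (1+4+9)/3 - 4 = 2/3
        a = M @ eff
        assert a.var() == pytest.approx(2 / 3)
        assert q["overall"][0, 0] == pytest.approx(1.0)

    def test_conservation_single_active_window(self):
        """All effects inside one window: q = 1 there, 0 elsewhere."""
        rng = RNG(2)
        M = rng.integers(0, 3, size=(30, 20)).astype(float)
        eff = np.zeros((20, 2))
        eff[5:10] = rng.normal(size=(5, 2))
        wt = define_windows(_map(20), 10)
        q = window_variance_proportions((eff, np.zeros_like(eff), eff), M, wt)
        np.testing.assert_allclose(q["overall"][0], [1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(q["overall"][1], [0.0, 0.0], atol=1e-12)

    def test_matches_independent_reimplementation(self):
        """q values agree with a from-scratch mean-of-squares computation."""
        rng = RNG(3)
        n, p, t = 20, 10, 2
        M = rng.integers(0, 3, size=(n, p)).astype(float)
        direct = rng.normal(size=(p, t))
        lam = np.array([[0.0, 0.0], [0.7, 0.0]])
        d, ind, ov = decompose_effects(direct, CausalStructure(lam))
        wt = define_windows(_map(p), 5)
        q = window_variance_proportions((d, ind, ov), M, wt)

        def naive_var(v):
            return float((v**2).mean() - v.mean() ** 2)

        a_tot = M @ ov
        for k in range(t):
            tot = naive_var(a_tot[:, k])
            for name, eff in (("direct", d), ("indirect", ind), ("overall", ov)):
                for w, (lo, hi) in enumerate([(0, 5), (5, 10)]):
                    expected = naive_var(M[:, lo:hi] @ eff[lo:hi, k]) / tot
                    assert q[name][w, k] == pytest.approx(expected, abs=1e-12)

    def test_batched_chain_version_agrees(self):
        rng = RNG(4)
        n, p, t, S = 15, 12, 2, 6
        M = rng.integers(0, 3, size=(n, p)).astype(float)
        chain = _fake_chain(rng, S, p, t, lam_val=0.5)
        wt = define_windows(_map(p), 4)
        compute_window_q(chain, M, wt)
        for s in range(S):
            lam = np.zeros((t, t))
            lam[1, 0] = chain.lam[s, 0]
            effs = decompose_effects(chain.alpha[s], CausalStructure(lam))
            single = window_variance_proportions(effs, M, wt)
            for name in ("direct", "indirect", "overall"):
                np.testing.assert_allclose(wt.q[name][s], single[name], atol=1e-12)


def _fake_chain(rng, S, p, t, lam_val=0.5):
    delta = (rng.random((S, p, t)) < 0.4).astype(np.uint8)
    alpha = rng.normal(size=(S, p, t)) * delta
    return ChainSamples(
        mu=np.zeros((S, t)),
        alpha=alpha,
        delta=delta,
        G=np.tile(np.eye(t), (S, 1, 1)),
        R=np.tile(np.eye(t), (S, 1, 1)),
        pi=np.tile(np.full(2**t, 1 / 2**t), (S, 1)),
        lam=np.full((S, 1), lam_val),
        support=[(1, 0)],
        iterations=np.arange(S),
        seed=0,
        trait_names=np.array([f"trait{k+1}" for k in range(t)], dtype=object),
    )


class TestWppa:
    def test_counting_strict_inequality(self):
        assert wppa(np.array([0.02, 0.005, 0.03]), 0.01) == pytest.approx(2 / 3)

    def test_ties_not_counted(self):
        """Samples exactly at T do not exceed it (strict >)."""
        assert wppa(np.array([0.01, 0.01, 0.02]), 0.01) == pytest.approx(1 / 3)

    def test_extremes(self):
        assert wppa(np.array([0.001, 0.002]), 0.01) == 0.0
        assert wppa(np.array([0.5, 0.9]), 0.01) == 1.0

    def test_monotone_nonincreasing_in_threshold(self):
        q = RNG(5).gamma(1.0, 0.02, size=500)
        ts = np.linspace(0, 0.1, 50)
        vals = [wppa(q, t) for t in ts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    def test_significant_windows_thresholds(self):
        wt = define_windows(_map(4), 2)
        wt.q = {"overall": RNG(0).random((10, 2, 1))}
        wt.wppa = {"overall": np.array([[0.9], [0.3]])}
        sig = significant_windows(wt, 0.8)
        np.testing.assert_array_equal(sig["overall"], [[True], [False]])
        assert significant_windows(wt, 0.0)["overall"].all()


class TestPleiotropy:
    def test_zero_lambda_overall_equals_direct_labels(self):
        rng = RNG(6)
        S, p, t = 8, 30, 2
        chain = _fake_chain(rng, S, p, t, lam_val=0.0)
        props = pleiotropy_proportions(chain)
        # with Lambda = 0, overall label frequencies equal the empirical
        # delta label frequencies (posterior mean Pi differs only by the
        # Dirichlet smoothing, so compare overall to the delta counts)
        from sembayes.bayescpi import label_counts

        freq = np.mean([label_counts(chain.delta[s].astype(float)) / p for s in range(S)], axis=0)
        np.testing.assert_allclose(props["overall"], freq, atol=1e-12)

    def test_causal_path_upgrades_label(self):
        """delta = (1, 0) at every sample with chain 1 -> 2 makes the
        overall combination {1, 2} certain."""
        S, p, t = 5, 1, 2
        delta = np.tile(np.array([[[1, 0]]], dtype=np.uint8), (S, 1, 1))
        chain = _fake_chain(RNG(7), S, p, t, lam_val=1.0)
        chain.delta = delta
        chain.alpha = delta.astype(float)
        props = pleiotropy_proportions(chain)
        np.testing.assert_allclose(props["overall"], [0, 0, 0, 1.0], atol=1e-12)

    def test_three_trait_reachability(self):
        """IC1-style chain: a locus with delta = (1,0,0) reaches all traits."""
        S, p, t = 3, 1, 3
        lam = np.zeros((t, t))
        lam[1, 0], lam[2, 0], lam[2, 1] = 0.5, 0.2, 0.3
        delta = np.tile(np.array([[[1, 0, 0]]], dtype=np.uint8), (S, 1, 1))
        chain = ChainSamples(
            mu=np.zeros((S, t)),
            alpha=delta.astype(float),
            delta=delta,
            G=np.tile(np.eye(t), (S, 1, 1)),
            R=np.tile(np.eye(t), (S, 1, 1)),
            pi=np.tile(np.full(8, 1 / 8), (S, 1)),
            lam=np.tile([0.5, 0.2, 0.3], (S, 1)),
            support=[(1, 0), (2, 0), (2, 1)],
            iterations=np.arange(S),
            seed=0,
            trait_names=np.array(["t1", "t2", "t3"], dtype=object),
        )
        props = pleiotropy_proportions(chain)
        assert props["overall"][7] == pytest.approx(1.0)  # label {1,2,3}
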