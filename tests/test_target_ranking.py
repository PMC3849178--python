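import numpy as np
import pytest
from scipy.integrate import dblquad, quad

from coopnet.synthetic_data import ode_response, tf_pulse
from coopnet.target_ranking import (
    LatentForceModel,
    fit_target,
    rank_genes,
    sim_cross_kernel,
    sim_kernel,
)


def quadrature_xx(t, tp, Sj, Dj, Sk, Dk, l):
    """Brute-force double quadrature oracle for the output-output kernel."""
    f = lambda v, u: np.exp(-Dj * (t - u)) * np.exp(-Dk * (tp - v)) * np.exp(-((u - v) ** 2) / l**2)
    val, _ = dblquad(f, 0, t, 0, tp, epsabs=1e-12, epsrel=1e-10)
    return Sj * Sk * val


def quadrature_xf(t, tp, S, D, l):
    f = lambda u: np.exp(-D * (t - u)) * np.exp(-((u - tp) ** 2) / l**2)
    val, _ = quad(f, 0, t, epsabs=1e-12, epsrel=1e-10)
    return S * val


class TestSimKernel:
    @pytest.mark.parametrize("t,tp,Dj,Dk,l", [
        (2.0, 4.0, 0.5, 0.5, 2.0),
        (3.0, 0.5, 1.5, 0.3, 1.0),
        (8.0, 2.0, 0.1, 2.0, 4.0),
        (5.0, 5.0, 3.0, 3.0, 0.5),
        (1.0, 7.0, 2.0, 0.4, 1.3),
    ])
    def test_matches_double_quadrature(self, t, tp, Dj, Dk, l):
        analytic = sim_kernel([t], [tp], 1.0, Dj, 0.7, Dk, l)[0, 0]
        oracle = quadrature_xx(t, tp, 1.0, Dj, 0.7, Dk, l)
        assert analytic == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("t,tp", [(2.0, 4.0), (4.0, 2.0), (3.0, 0.0), (6.0, 8.0)])
    def test_cross_kernel_matches_quadrature(self, t, tp):
        analytic = sim_cross_kernel([t], [tp], 1.5, 0.5, 2.0)[0, 0]
        assert analytic == pytest.approx(quadrature_xf(t, tp, 1.5, 0.5, 2.0), rel=1e-6)

    def test_zero_sensitivity_means_zero_covariance(self):
        t = np.linspace(0, 8, 5)
        K = sim_kernel(t, t, 0.0, 0.5, 0.0, 0.5, 2.0)
        np.testing.assert_allclose(K, 0.0, atol=1e-15)

    def test_fast_decay_kills_covariance(self):
        small = sim_kernel([2.0], [2.0], 1.0, 50.0, 1.0, 50.0, 2.0)[0, 0]
        large = sim_kernel([2.0], [2.0], 1.0, 0.5, 1.0, 0.5, 2.0)[0, 0]
        assert small < 1e-2 * large

    def test_gram_matrices_positive_semidefinite(self, rng):
        for S, D, l in [(1.0, 0.5, 2.0), (2.0, 3.0, 0.7), (0.3, 0.05, 6.0)]:
            t = np.sort(rng.uniform(0, 10, 30))
            K = sim_kernel(t, t, S, D, S, D, l)
            eig = np.linalg.eigvalsh(K + 1e-8 * np.eye(30))
            assert eig.min() >= -1e-8

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            sim_kernel([1.0], [1.0], 1.0, -0.5, 1.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            sim_cross_kernel([1.0], [1.0], 1.0, 0.5, 0.0)


def dense_fixture(B=1.0, S=2.0, D=0.8, noise=0.05, n=16, seed=0):
    rng = np.random.default_rng(seed)
    tobs = np.linspace(0, 8, n)
    yf = tf_pulse(tobs) + rng.normal(0, noise, n)
    yg = ode_response(tobs, B, S, D, B / D) + rng.normal(0, noise, n)
    return tobs, yf, yg


class TestFitTarget:
    def test_parameter_recovery_dense_low_noise(self):
        B, S, D = 1.0, 2.0, 0.8
        tobs, yf, yg = dense_fixture(B, S, D)
        params, score = fit_target(tobs, yf, tobs, yg, "g1")
        assert params.B == pytest.approx(B, rel=0.2)
        assert params.S == pytest.approx(S, rel=0.2)
        assert params.D == pytest.approx(D, rel=0.2)
        assert score.score > 10

    def test_flat_gene_scores_near_zero(self):
        rng = np.random.default_rng(3)
        tobs = np.repeat([0.0, 2.0, 4.0, 8.0], 4)
        yf = tf_pulse(tobs) + rng.normal(0, 0.25, 16)
        for seed in range(5):
            r2 = np.random.default_rng(seed + 10)
            yg = 2.0 + r2.normal(0, 0.25, 16)
            _, score = fit_target(tobs, yf, tobs, yg)
            assert abs(score.score) < 2.0

    def test_constant_tf_and_gene_null_equivalent(self):
        tobs = np.repeat([0.0, 2.0, 4.0, 8.0], 2)
        rng = np.random.default_rng(5)
        yf = 1.0 + rng.normal(0, 0.01, 8)
        yg = 2.0 + rng.normal(0, 0.01, 8)
        _, score = fit_target(tobs, yf, tobs, yg)
        assert abs(score.score) < 2.0

    def test_alt_never_worse_than_null(self):
        tobs, yf, yg = dense_fixture(seed=9)
        res = LatentForceModel(tobs, yf, tobs, yg).fit("g")
        assert res.ll_alt >= res.ll_null - 1e-6

    def test_score_invariant_to_constant_shift(self):
        tobs, yf, yg = dense_fixture(seed=4)
        _, s1 = fit_target(tobs, yf, tobs, yg)
        _, s2 = fit_target(tobs, yf, tobs, yg + 5.0)
        assert s1.score == pytest.approx(s2.score, abs=0.5)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            LatentForceModel([0, 0, 2, 2], [1, 1, 2, 2], [0, 0, 2, 2], [1, 2, 3, 4])

    def test_summary_mentions_estimates(self):
        tobs, yf, yg = dense_fixture(seed=2)
        res = LatentForceModel(tobs, yf, tobs, yg).fit("gene7")
        text = res.summary()
        assert "gene7" in text and "decay rate D" in text


@pytest.fixture(scope="module")
def small_ranking():
    """12 genes (4 targets) under the 4-time-point x 4-replicate design."""
    rng = np.random.default_rng(21)
    tp = np.array([0.0, 2.0, 4.0, 8.0])
    import pandas as pd

    from coopnet.formats_io import ExpressionMatrix
    samples = [{"sample": f"s{t:g}_{r}", "condition": "WKY", "time_h": t, "replicate": r}
               for t in tp for r in range(1, 5)]
    sheet = pd.DataFrame(samples).set_index("sample")
    tobs = sheet["time_h"].to_numpy()
    rows, genes = [], []
    genes.append("TF"); rows.append(tf_pulse(tobs) + rng.normal(0, 0.25, 16))
    for i in range(4):
        D = rng.uniform(0.3, 1.5); S = rng.uniform(0.8, 2.0); base = rng.uniform(1, 3)
        mu = ode_response(tp, base * D, S, D, base)
        rows.append(np.repeat(mu, 4) + rng.normal(0, 0.25, 16))
        genes.append(f"target{i}")
    for i in range(7):
        rows.append(rng.uniform(1, 3) + rng.normal(0, 0.25, 16))
        genes.append(f"null{i}")
    data = pd.DataFrame(np.vstack(rows), index=genes, columns=sheet.index)
    expr = ExpressionMatrix(data, sheet)
    return expr, rank_genes(expr, "TF", condition="WKY")


class TestRankGenes:
    def test_targets_outrank_nulls(self, small_ranking):
        _, scores = small_ranking
        ranked = [s.gene_id for s in scores]
        assert set(ranked[:4]) == {f"target{i}" for i in range(4)}

    def test_one_score_per_non_tf_gene(self, small_ranking):
        expr, scores = small_ranking
        assert len(scores) == len(expr.genes) - 1
        assert all(s.gene_id != "TF" for s in scores)

    def test_missing_tf_rejected(self, small_ranking):
        expr, _ = small_ranking
        with pytest.raises(KeyError, match="nosuch"):
            rank_genes(expr, "nosuch")
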