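import numpy as np
import pandas as pd
import pytest

from m6apattern import scoring
from m6apattern import survival as sv
from m6apattern.datatypes import ClinicalTable, ExpressionMatrix
from m6apattern.simulate import (SimulationParams, simulate_expression,
                                 simulate_survival)


def _em(arr, genes=None, samples=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            unit="zscore")


def _manual_model(genes, w1, w2, betas, mean=None, sd=None):
    idx = pd.Index(genes)
    return scoring.SignatureModel(
        genes=list(genes),
        cox_coef=pd.Series(betas, index=idx),
        cox_p=pd.Series(0.01, index=idx),
        mean=pd.Series(mean if mean is not None else 0.0, index=idx),
        sd=pd.Series(sd if sd is not None else 1.0, index=idx),
        w1=pd.Series(w1, index=idx),
        w2=pd.Series(w2, index=idx),
        explained_variance_ratio=(0.6, 0.4),
    )


class TestCoxFilter:
    def test_true_score_gene_retained_with_positive_beta(self):
        p = SimulationParams(n_samples=500, hazard_beta=1.0, seed=21)
        expr, truth = simulate_expression(p)
        clin = simulate_survival(truth, p)
        vals = expr.values.copy()
        vals.loc["oracle_gene"] = truth.true_score.to_numpy()
        m2 = ExpressionMatrix(vals, unit="zscore")
        kept, betas, _ = scoring.cox_filter(["oracle_gene"] + truth.noise_genes,
                                            m2, clin)
        assert "oracle_gene" in kept
        assert betas["oracle_gene"] > 0

    def test_noise_gene_type_one_error_rate(self):
        """Pure-noise genes pass the p<0.05 screen at roughly the nominal rate."""
        p = SimulationParams(n_samples=500, n_noise_genes=400, hazard_beta=1.0, seed=22)
        expr, truth = simulate_expression(p)
        clin = simulate_survival(truth, p)
        X = expr.values.loc[truth.noise_genes].to_numpy().T
        _, _, pvals = sv.cox_univariate_batch(clin.time, clin.event, X)
        frac = (pvals < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_zero_variance_gene_skipped(self, caplog):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(3, 30))
        arr[1] = 7.0
        m = _em(arr)
        clin = ClinicalTable(pd.DataFrame(
            {"time": rng.exponential(10, 30) + 0.1, "event": 1},
            index=m.sample_ids))
        with caplog.at_level("WARNING"):
            kept, _, _ = scoring.cox_filter(["g0", "g1", "g2"], m, clin,
                                            p_threshold=1.0)
        assert "g1" not in kept and "zero-variance" in caplog.text

    def test_nothing_passes_is_error(self):
        rng = np.random.default_rng(1)
        m = _em(rng.normal(size=(3, 40)))
        clin = ClinicalTable(pd.DataFrame(
            {"time": rng.exponential(10, 40) + 0.1, "event": 1},
            index=m.sample_ids))
        with pytest.raises(ValueError, match="threshold"):
            scoring.cox_filter(["g0", "g1", "g2"], m, clin, p_threshold=1e-12)


class TestFitPcaSignature:
    def test_two_identical_genes_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        m = _em(np.vstack([x, x]))
        with pytest.raises(ValueError, match="rank 1"):
            scoring.fit_pca_signature(m)

    def test_two_nearly_identical_genes_w1_diagonal(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        m = _em(np.vstack([x, x + 1e-3 * rng.normal(size=200)]))
        model = scoring.fit_pca_signature(m)
        assert np.allclose(np.abs(model.w1.to_numpy()), 1 / np.sqrt(2), atol=1e-3)

    def test_uncorrelated_genes_recover_axes(self):
        rng = np.random.default_rng(4)
        m = _em(rng.normal(size=(2, 2000)))
        model = scoring.fit_pca_signature(m)
        evr = model.explained_variance_ratio
        assert abs(evr[0] - 0.5) <= 0.05 and abs(evr[1] - 0.5) <= 0.05
        # with an isotropic population covariance the loading basis is an
        # arbitrary rotation; it must still be an orthonormal 2x2 basis
        W = np.vstack([model.w1.to_numpy(), model.w2.to_numpy()])
        assert np.allclose(W @ W.T, np.eye(2), atol=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(5)
        m = _em(rng.normal(size=(8, 100)))
        model = scoring.fit_pca_signature(m)
        w1, w2 = model.w1.to_numpy(), model.w2.to_numpy()
        assert np.linalg.norm(w1) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(w2) == pytest.approx(1.0, abs=1e-9)
        assert abs(w1 @ w2) <= 1e-9

    def test_needs_two_genes_three_samples(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="2 genes"):
            scoring.fit_pca_signature(_em(rng.normal(size=(1, 10))))
        with pytest.raises(ValueError, match="3 samples"):
            scoring.fit_pca_signature(_em(rng.normal(size=(3, 2))))


class TestScoreFormulas:
    def test_formula_a_identity_loadings(self):
        model = _manual_model(["g1", "g2"], w1=[1.0, 0.0], w2=[0.0, 1.0],
                              betas=[1.0, -1.0])
        m = _em(np.array([[1.0], [-1.0]]), genes=["g1", "g2"], samples=["s"])
        assert scoring.score_formula_A(model, m)["s"] == pytest.approx(0.0)
        m2 = _em(np.array([[1.0], [1.0]]), genes=["g1", "g2"], samples=["s"])
        assert scoring.score_formula_A(model, m2)["s"] == pytest.approx(2.0)

    def test_formula_b_hand_example(self):
        model = _manual_model(["g1", "g2"], w1=[1.0, 0.0], w2=[0.0, 1.0],
                              betas=[1.0, -1.0])
        m = _em(np.array([[1.0], [5.0]]), genes=["g1", "g2"], samples=["s"])
        # G+={g1}, G-={g2}: 1*1 - 5*0 = 1
        assert scoring.score_formula_B(model, m)["s"] == pytest.approx(1.0)

    def test_formula_b_all_positive_equals_pc1_projection(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(4)]
        w1 = rng.normal(size=4)
        w1 /= np.linalg.norm(w1)
        model = _manual_model(genes, w1=w1, w2=np.roll(w1, 1), betas=[1.0] * 4)
        m = _em(rng.normal(size=(4, 10)), genes=genes)
        b = scoring.score_formula_B(model, m)
        pc1 = m.values.to_numpy().T @ w1
        assert np.allclose(b.to_numpy(), pc1, atol=1e-12)

    def test_random_instance_matches_double_sum_oracle(self):
        rng = np.random.default_rng(8)
        g = 6
        genes = [f"g{i}" for i in range(g)]
        W = np.linalg.qr(rng.normal(size=(g, 2)))[0]
        mean = rng.normal(size=g)
        sd = rng.uniform(0.5, 2.0, g)
        betas = rng.normal(size=g)
        model = _manual_model(genes, w1=W[:, 0], w2=W[:, 1], betas=betas,
                              mean=mean, sd=sd)
        m = _em(rng.normal(size=(g, 5)), genes=genes)
        got_a = scoring.score_formula_A(model, m)
        got_b = scoring.score_formula_B(model, m)
        X = m.values.to_numpy()
        for si, sample in enumerate(m.sample_ids):
            z = (X[:, si] - mean) / sd
            score_a = sum(z[j] * W[j, k] for k in range(2) for j in range(g))
            score_b = (sum(z[j] * W[j, 0] for j in range(g) if betas[j] > 0)
                       - sum(z[j] * W[j, 0] for j in range(g) if betas[j] < 0))
            assert got_a[sample] == pytest.approx(score_a, abs=1e-12)
            assert got_b[sample] == pytest.approx(score_b, abs=1e-12)

    def test_missing_gene_is_hard_error(self):
        model = _manual_model(["g1", "g2"], [1, 0], [0, 1], [1, 1])
        m = _em(np.ones((1, 2)), genes=["g1"])
        with pytest.raises(KeyError, match="g2"):
            scoring.score_formula_A(model, m)

    def test_empty_sign_groups_error(self):
        model = _manual_model(["g1", "g2"], [1, 0], [0, 1], [0.0, 0.0])
        m = _em(np.ones((2, 2)), genes=["g1", "g2"])
        with pytest.raises(ValueError, match="signed Cox"):
            scoring.score_formula_B(model, m)


class TestInvariances:
    def _fitted(self, seed=30, n=300):
        p = SimulationParams(n_samples=n, hazard_beta=1.0, seed=seed)
        expr, truth = simulate_expression(p)
        clin = simulate_survival(truth, p)
        model = scoring.fit_signature(truth.signature_genes, expr, clin)
        return expr, clin, truth, model

    def test_sign_convention_flip_invariance(self):
        """Negating a loading vector and re-applying the orientation rule
        reproduces identical scores."""
        expr, _, _, model = self._fitted()
        flipped = _manual_model(model.genes,
                                w1=-model.w1.to_numpy(), w2=-model.w2.to_numpy(),
                                betas=model.cox_coef.to_numpy(),
                                mean=model.mean.to_numpy(), sd=model.sd.to_numpy())
        # re-fix: orientation makes the Cox-implied risk direction positive
        for w in (flipped.w1, flipped.w2):
            if float(flipped.cox_coef @ w) < 0:
                w *= -1.0
        assert np.allclose(scoring.score_formula_A(model, expr),
                           scoring.score_formula_A(flipped, expr), atol=1e-12)

    def test_affine_rescaling_invariance(self):
        expr, clin, truth, model = self._fitted(seed=31)
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 3.0, expr.n_genes)
        b = rng.normal(size=expr.n_genes)
        rescaled = ExpressionMatrix(expr.values.mul(a, axis=0).add(b, axis=0),
                                    unit=expr.unit)
        model2 = scoring.fit_signature(truth.signature_genes, rescaled, clin)
        s1 = scoring.score_formula_A(model, expr)
        s2 = scoring.score_formula_A(model2, rescaled)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_planted_score_recovered(self):
        rhos = []
        for seed in (32, 33):
            p = SimulationParams(n_samples=500, hazard_beta=1.0, seed=seed)
            expr, truth = simulate_expression(p)
            clin = simulate_survival(truth, p)
            model = scoring.fit_signature(truth.signature_genes, expr, clin)
            s = scoring.score_formula_A(model, expr)
            rho, _ = sv.spearman(s.to_numpy(), truth.true_score.to_numpy())
            rhos.append(rho)
        assert np.mean(rhos) >= 0.8
        assert min(rhos) >= 0.7


class TestBootstrapSelection:
    def test_deterministic_given_seed(self):
        p = SimulationParams(n_samples=200, hazard_beta=1.0, seed=40)
        expr, truth = simulate_expression(p)
        clin = simulate_survival(truth, p)
        s1 = scoring.bootstrap_select_formula(truth.signature_genes, expr, clin,
                                              n_iter=8, seed=5)
        s2 = scoring.bootstrap_select_formula(truth.signature_genes, expr, clin,
                                              n_iter=8, seed=5)
        assert np.array_equal(s1.cindex_traces["A"], s2.cindex_traces["A"])
        assert np.array_equal(s1.cindex_traces["B"], s2.cindex_traces["B"])

    def test_null_hazard_gives_chance_cindex(self):
        p = SimulationParams(n_samples=400, hazard_beta=0.0, seed=41)
        expr, truth = simulate_expression(p)
        clin = simulate_survival(truth, p)
        sel = scoring.bootstrap_select_formula(truth.signature_genes, expr, clin,
                                               n_iter=20, seed=1, p_threshold=0.8)
        assert 0.45 <= sel.mean_cindex["A"] <= 0.55
        assert 0.45 <= sel.mean_cindex["B"] <= 0.55

    def test_selects_formula_a_under_planted_two_component_hazard(self):
        p = SimulationParams(n_samples=300, hazard_beta=1.0, seed=42)
        expr, truth = simulate_expression(p)
        clin = simulate_survival(truth, p)
        sel = scoring.bootstrap_select_formula(truth.signature_genes, expr, clin,
                                               n_iter=15, seed=2)
        assert sel.formula == "A"
        assert sel.mean_cindex["A"] > sel.mean_cindex["B"]


class TestRegulatorNetwork:
    def test_planted_block_edges_and_risk_annotation(self):
        rng = np.random.default_rng(9)
        n = 300
        latent = rng.normal(size=n)
        block = np.vstack([latent + 0.4 * rng.normal(size=n) for _ in range(3)])
        indep = rng.normal(size=(3, n))
        arr = np.vstack([block, indep])
        genes = [f"W{i}" for i in range(3)] + [f"I{i}" for i in range(3)]
        m = _em(arr, genes=genes)
        lam = 0.002 * np.exp(latent)
        t = rng.exponential(1 / lam)
        clin = ClinicalTable(pd.DataFrame({"time": t, "event": 1},
                                          index=m.sample_ids))
        edges, annot = scoring.regulator_network(m, clin)
        within = edges[(edges.gene_a.str.startswith("W"))
                       & (edges.gene_b.str.startswith("W"))]
        assert len(within) == 3  # all writer-block pairs retained
        assert (annot.loc[["W0", "W1", "W2"], "role"] == "risk").all()

    def test_null_edge_rate_near_nominal(self):
        rng = np.random.default_rng(10)
        m = _em(rng.normal(size=(30, 100)))
        clin = ClinicalTable(pd.DataFrame(
            {"time": rng.exponential(10, 100) + 0.01, "event": 1},
            index=m.sample_ids))
        edges, _ = scoring.regulator_network(m, clin)
        n_pairs = 30 * 29 / 2
        assert 0.005 <= len(edges) / n_pairs <= 0.12

    def test_too_few_genes_error(self):
        rng = np.random.default_rng(11)
        m = _em(rng.normal(size=(1, 20)))
        clin = ClinicalTable(pd.DataFrame(
            {"time": rng.exponential(10, 20) + 0.01, "event": 1},
            index=m.sample_ids))
        with pytest.raises(ValueError, match="2 genes"):
            scoring.regulator_network(m, clin)
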