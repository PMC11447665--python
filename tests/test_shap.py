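"""Zone Shapley values: axioms, brute-force oracle, sampling convergence."""

import itertools
import math

import numpy as np
import pytest

from zonexplain import (
    ModelAdapter,
    SpectraSet,
    Spectrum,
    exact_zone_shap,
    explain_dataset,
    sampling_zone_shap,
)
from zonexplain.synthetic import toy_zone_model

from conftest import constant_model, make_zones


def brute_force_shap(value_fn, n):
    """Independent oracle: textbook Shapley formula by subset enumeration."""
    phi = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for r in range(n):
            for S in itertools.combinations(others, r):
                w = math.factorial(len(S)) * math.factorial(n - len(S) - 1) / math.factorial(n)
                phi[i] += w * (value_fn(set(S) | {i}) - value_fn(set(S)))
    return phi


@pytest.fixture
def toy_setup(grid100):
    """A 3-zone instance with an identity-link linear model on zone means."""
    zs = make_zones(grid100, [30, 70])
    rng = np.random.default_rng(0)
    x = Spectrum(grid100, rng.uniform(0.2, 1.0, 100), id="toy")
    w = np.array([0.8, -0.5, 0.3])
    model = toy_zone_model(w, zs, link="identity")
    return zs, x, w, model


class TestExactShap:
    def test_constant_model_all_zero(self, instance, three_zones, reference):
        att = exact_zone_shap(constant_model(0.3), instance, three_zones,
                              "reference_mean", reference)
        np.testing.assert_allclose(att.values, 0.0, atol=1e-12)

    def test_single_zone_is_marginal(self, grid100, reference):
        zs = make_zones(grid100, [])
        rng = np.random.default_rng(1)
        x = Spectrum(grid100, rng.uniform(size=100))
        model = toy_zone_model(np.array([2.0]), zs, link="identity")
        att = exact_zone_shap(model, x, zs, "reference_mean", reference)
        fx = model.predict(x.intensities[None, :])[0, 0]
        f0 = model.predict(reference.matrix.mean(axis=0)[None, :])[0, 0]
        assert att.values[0] == pytest.approx(fx - f0, abs=1e-12)

    def test_matches_closed_form_and_brute_force(self, toy_setup):
        """Linear model, zero baseline: phi_i = w_i * mean_i(x) two ways."""
        zs, x, w, model = toy_setup
        att = exact_zone_shap(model, x, zs, baseline="zero")
        closed = w * zs.zone_means(x.intensities[None, :])[0]
        np.testing.assert_allclose(att.values, closed, atol=1e-9)

        def value_fn(S):
            masked = np.zeros(100)
            for k in S:
                z = zs[k]
                masked[z.start : z.end] = x.intensities[z.start : z.end]
            return float(model.predict(masked[None, :])[0, 0])

        np.testing.assert_allclose(att.values, brute_force_shap(value_fn, 3),
                                   atol=1e-9)

    def test_efficiency_axiom_nonlinear_model(self, instance, three_zones,
                                              reference):
        zs = three_zones

        def predict(X):
            m = zs.zone_means(X)
            p = 1 / (1 + np.exp(-(m[:, 0] * m[:, 1] - m[:, 2] ** 2)))
            return np.column_stack([p, 1 - p])

        model = ModelAdapter(predict_fn=predict, class_names=["a", "b"])
        att = exact_zone_shap(model, instance, zs, "reference_mean", reference)
        assert att.values.sum() == pytest.approx(att.prediction - att.base_value,
                                                 abs=1e-9)

    def test_symmetry_axiom(self, grid100, reference):
        """Two zones with identical effect on the model get equal phi."""
        zs = make_zones(grid100, [30, 70])
        # symmetric weights on zones 0 and 2; make their content identical
        y = np.zeros(100)
        y[:30] = 0.6
        y[70:] = 0.6
        y[30:70] = 0.9
        x = Spectrum(grid100, y)
        # zones 0 and 2 must be interchangeable in the value function: use a
        # model symmetric in (mean_0, mean_2)
        def predict(X):
            m = zs.zone_means(X)
            return (m[:, 0] + m[:, 2] + 0.5 * m[:, 1]).reshape(-1, 1)

        model = ModelAdapter(predict_fn=predict, class_names=["s"], strict=False)
        ref = SpectraSet(grid=grid100, matrix=np.full((2, 100), 0.1))
        att = exact_zone_shap(model, x, zs, "reference_mean", ref)
        assert att.values[0] == pytest.approx(att.values[2], abs=1e-9)

    def test_dummy_axiom(self, toy_setup, reference):
        zs, x, _, _ = toy_setup
        model = toy_zone_model(np.array([1.0, 0.0, -1.0]), zs, link="identity")
        att = exact_zone_shap(model, x, zs, "reference_mean", reference)
        assert att.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_zone_cap_enforced(self, instance, reference):
        zs = make_zones(instance.grid, list(range(4, 96, 4)))
        with pytest.raises(ValueError, match="sampling_zone_shap"):
            exact_zone_shap(constant_model(), instance, zs, "reference_mean",
                            reference, cap=20)

    def test_memoization_single_call_per_coalition(self, toy_setup):
        zs, x, _, model = toy_setup
        calls = []
        counted = ModelAdapter(
            predict_fn=lambda X: (calls.append(len(X)) or model.predict_fn(X)),
            class_names=model.class_names, strict=False,
        )
        exact_zone_shap(counted, x, zs, baseline="zero")
        assert sum(calls) == 2 ** len(zs)


class TestSamplingShap:
    def test_constant_model_zero_values_zero_stderr(self, instance, three_zones,
                                                    reference):
        att = sampling_zone_shap(constant_model(0.4), instance, three_zones,
                                 "reference_mean", reference, n_draws=50, seed=0)
        np.testing.assert_allclose(att.values, 0.0, atol=1e-12)
        np.testing.assert_allclose(att.stderr, 0.0, atol=1e-12)

    def test_agrees_with_exact_within_4_stderr(self, grid100, reference):
        """8-zone softmax model: sampling estimate brackets the exact value."""
        zs = make_zones(grid100, [12, 25, 37, 50, 62, 75, 88])
        rng = np.random.default_rng(2)
        W = rng.normal(scale=1.5, size=(3, 8))
        model = toy_zone_model(W, zs, link="softmax")
        x = Spectrum(grid100, rng.uniform(0.0, 1.0, 100))
        exact = exact_zone_shap(model, x, zs, "reference_mean", reference,
                                class_index=1)
        approx = sampling_zone_shap(model, x, zs, "reference_mean", reference,
                                    class_index=1, n_draws=5000, seed=9)
        err = np.abs(approx.values - exact.values)
        tol = 4 * approx.stderr + 1e-12
        assert np.all(err < tol), (err, tol)

    def test_determinism_contract(self, grid100, reference):
        zs = make_zones(grid100, [30, 50, 70])
        rng = np.random.default_rng(4)
        model = toy_zone_model(rng.normal(size=(2, 4)), zs, link="softmax")
        x = Spectrum(grid100, rng.uniform(size=100))
        kw = dict(baseline="reference_mean", reference=reference, n_draws=200)
        a = sampling_zone_shap(model, x, zs, seed=5, **kw)
        b = sampling_zone_shap(model, x, zs, seed=5, **kw)
        c = sampling_zone_shap(model, x, zs, seed=6, **kw)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        np.testing.assert_allclose(a.values, c.values, atol=0.2)

    def test_min_draws_enforced(self, instance, three_zones, reference):
        with pytest.raises(ValueError, match="n_draws"):
            sampling_zone_shap(constant_model(), instance, three_zones,
                               "reference_mean", reference, n_draws=2, seed=0)

    def test_rmse_decreases_with_draws(self, grid100, reference):
        """Monte-Carlo error shrinks roughly like N^-1/2."""
        zs = make_zones(grid100, [20, 40, 60, 80])
        rng = np.random.default_rng(8)
        model = toy_zone_model(rng.normal(size=(2, 5)), zs, link="softmax")
        x = Spectrum(grid100, rng.uniform(size=100))
        exact = exact_zone_shap(model, x, zs, "reference_mean", reference)
        rmse = []
        for n in (500, 2000, 8000):
            approx = sampling_zone_shap(model, x, zs, "reference_mean",
                                        reference, n_draws=n, seed=1)
            rmse.append(float(np.sqrt(np.mean((approx.values - exact.values) ** 2))))
        assert rmse[2] < rmse[0]

    def test_efficiency_within_sampling_error(self, grid100, reference):
        zs = make_zones(grid100, [15, 35, 55, 75])
        rng = np.random.default_rng(12)
        model = toy_zone_model(rng.normal(size=(2, 5)), zs, link="softmax")
        x = Spectrum(grid100, rng.uniform(size=100))
        att = sampling_zone_shap(model, x, zs, "reference_mean", reference,
                                 n_draws=1000, seed=3)
        gap = abs(att.values.sum() - (att.prediction - att.base_value))
        assert gap < 4 * np.sqrt(np.sum(att.stderr**2)) + 1e-9


class TestExplainDataset:
    def test_singleton_matches_single_instance_call(self, grid100, reference):
        zs = make_zones(grid100, [40])
        rng = np.random.default_rng(3)
        model = toy_zone_model(rng.normal(size=(2, 2)), zs, link="softmax")
        row = rng.uniform(size=100)
        ds = SpectraSet(grid=grid100, matrix=row[None, :], ids=["only"])
        atts = explain_dataset(model, ds, zs, "reference_mean", reference,
                               method="exact_shap", seed=0)
        single = exact_zone_shap(model, ds.spectrum(0), zs, "reference_mean",
                                 reference)
        assert len(atts) == 1
        np.testing.assert_allclose(atts[0].values, single.values, atol=1e-12)

    def test_row_permutation_permutes_results(self, grid100, reference):
        zs = make_zones(grid100, [30, 60])
        rng = np.random.default_rng(6)
        model = toy_zone_model(rng.normal(size=(2, 3)), zs, link="softmax")
        ds = SpectraSet(grid=grid100, matrix=rng.uniform(size=(5, 100)),
                        ids=[f"s{i}" for i in range(5)])
        atts = explain_dataset(model, ds, zs, "reference_mean", reference,
                               n_draws=100, seed=2)
        perm = [3, 1, 4, 0, 2]
        atts_p = explain_dataset(model, ds.subset(perm), zs, "reference_mean",
                                 reference, n_draws=100, seed=2)
        for k, orig in enumerate(perm):
            np.testing.assert_array_equal(atts_p[k].values, atts[orig].values)

    def test_mean_abs_ranking_matches_per_spectrum_oracle(self, grid100,
                                                          reference):
        zs = make_zones(grid100, [25, 50, 75])
        rng = np.random.default_rng(10)
        model = toy_zone_model(rng.normal(size=(2, 4)), zs, link="softmax")
        ds = SpectraSet(grid=grid100, matrix=rng.uniform(size=(12, 100)),
                        ids=[f"s{i}" for i in range(12)])
        atts = explain_dataset(model, ds, zs, "reference_mean", reference,
                               method="exact_shap", seed=0)
        # oracle: direct per-spectrum recomputation
        oracle = [
            exact_zone_shap(model, ds.spectrum(i), zs, "reference_mean", reference)
            for i in range(12)
        ]
        rank = np.argsort(-np.abs(np.stack([a.values for a in atts])).mean(axis=0))
        rank_o = np.argsort(-np.abs(np.stack([a.values for a in oracle])).mean(axis=0))
        np.testing.assert_array_equal(rank, rank_o)
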