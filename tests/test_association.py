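import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scipac.association import (association_strength, perturbed_bulk_profile,
                                sample_specific_strength,
                                standardize_strengths)
from scipac.regression import linear_predictor


class TestAssociationStrength:
    def test_dot_product_arithmetic(self):
        lam = association_strength(np.array([1.0, -1.0]),
                                   np.array([[2.0, 0.0]]),
                                   np.array([1.0, 1.0]))
        assert lam[0] == pytest.approx(2.0)

    def test_centroid_at_bulk_mean_is_zero(self, rng):
        g = rng.normal(size=(1, 5))
        assert association_strength(rng.normal(size=5), g, g[0])[0] == 0.0

    def test_zero_beta_zero_everywhere(self, rng):
        lam = association_strength(np.zeros(4), rng.normal(size=(3, 4)),
                                   rng.normal(size=4))
        np.testing.assert_array_equal(lam, np.zeros(3))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            association_strength(np.ones(3), np.ones((2, 4)), np.ones(4))

    def test_moving_centroid_along_beta_increases_strength(self, rng):
        beta = rng.normal(size=6)
        g = rng.normal(size=6)
        bulk_mean = rng.normal(size=6)
        lams = [association_strength(beta, (g + t * beta)[None, :], bulk_mean)[0]
                for t in (0.0, 0.5, 1.0)]
        assert lams[0] < lams[1] < lams[2]


class TestSampleSpecific:
    def test_arithmetic(self):
        assert sample_specific_strength(np.array([2.0]), np.array([3.0]),
                                        np.array([1.0])) == 4.0

    def test_zero_when_sample_equals_centroid(self, rng):
        g = rng.normal(size=4)
        assert sample_specific_strength(rng.normal(size=4), g, g.copy()) == 0.0

    def test_mean_over_samples_equals_average_strength(self, rng):
        beta = rng.normal(size=5)
        g = rng.normal(size=5)
        G = rng.normal(size=(20, 5))
        per_sample = [sample_specific_strength(beta, g, Gi) for Gi in G]
        lam = association_strength(beta, g[None, :], G.mean(axis=0))[0]
        assert np.mean(per_sample) == pytest.approx(lam, rel=1e-12)


class TestStandardize:
    def test_two_points(self):
        out = standardize_strengths(np.array([1.0, 3.0]))
        np.testing.assert_allclose(out, [-0.7071, 0.7071], atol=1e-4)

    def test_constant_input_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="identical"):
            out = standardize_strengths(np.full(5, 2.5))
        np.testing.assert_array_equal(out, np.zeros(5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=8)
        np.testing.assert_allclose(
            standardize_strengths(a * x + b), standardize_strengths(x),
            atol=1e-8)

    def test_mean_zero_sd_one(self, rng):
        out = standardize_strengths(rng.normal(3, 2, size=100))
        assert out.mean() == pytest.approx(0.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestPerturbationIdentity:
    """The fitted log-odds shift under over-representation of a cluster is
    proportional to beta' (g_k - G_i) — the model's central identity."""

    def test_identity_on_fitted_model(self, tiny_run):
        ds, res = tiny_run
        fit = res.regression_fit
        bulk = res.model.bulk
        cen = res.centroids.values
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(0, cen.shape[0])
            i = rng.integers(0, bulk.n_obs)
            dg = rng.uniform(0.01, 5.0)
            G = bulk.values[i]
            G_star = perturbed_bulk_profile(G, cen[k], dg)
            lhs = (linear_predictor(fit, G_star[None, :])[0]
                   - linear_predictor(fit, G[None, :])[0])
            rhs = dg / (1 + dg) * float(fit.beta @ (cen[k] - G))
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_perturbed_profile_stays_in_convex_hull(self, rng):
        G = rng.uniform(0, 5, 10)
        g = rng.uniform(0, 5, 10)
        out = perturbed_bulk_profile(G, g, 1.0)
        np.testing.assert_allclose(out, (G + g) / 2)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            perturbed_bulk_profile(np.ones(3), np.ones(3), -0.1)


def test_strengths_shared_within_cluster(tiny_run):
    _, res = tiny_run
    lam = res.association.lambda_std
    for k in range(1, res.labels.K + 1):
        vals = lam[res.labels.assignments == k]
        assert np.all(vals == vals[0])


def test_association_invariant_to_cell_order(tiny_run):
    ds, res = tiny_run
    from scipac import SCIPAC

    perm = np.random.default_rng(1).permutation(ds.sc.n_obs)
    sc_perm = type(ds.sc)(ds.sc.values[perm],
                          [ds.sc.obs_ids[i] for i in perm],
                          list(ds.sc.gene_ids))
    res2 = SCIPAC(sc_perm, ds.bulk, ds.pheno,
                  cell_labels=ds.cell_types[perm]).fit(bootstrap_reps=5, seed=7)
    lam1 = dict(zip(res.frame["cell_id"], res.frame["Lambda"]))
    lam2 = dict(zip(res2.frame["cell_id"], res2.frame["Lambda"]))
    for cid, v in lam2.items():
        assert v == pytest.approx(lam1[cid], abs=1e-9)
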