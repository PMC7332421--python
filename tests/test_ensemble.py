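import numpy as np
import pandas as pd
import pytest

from conftest import random_distribution
from edudist._utils import BIN_YEARS, logit
from edudist.ensemble import (
    CandidateLibrary,
    EnsembleConfig,
    build_library,
    ensemble_average,
    ensemble_weights,
    loess_smooth_bins,
    mahalanobis_select,
    reconstruct_series,
)


def make_library(rng, n=200, cov=None):
    bins = random_distribution(rng, n=n)
    means = bins @ BIN_YEARS
    features = np.column_stack([logit(means / 18.0), logit(bins[:, 0])])
    meta = pd.DataFrame({
        "location_id": rng.choice(["A", "B", "C", "D"], n),
        "age": rng.choice([27.0, 32.0, 37.0], n),
        "cohort": rng.integers(1940, 1995, n).astype(float),
        "provider": "prov",
    })
    return CandidateLibrary(features=features, bins=bins, meta=meta, cov=cov)


class TestMahalanobisSelect:
    def test_identity_covariance_matches_euclidean_order(self, rng):
        lib = make_library(rng, cov=np.eye(2))
        q = np.array([0.0, -1.0])
        idx, _ = mahalanobis_select(q, lib, 10)
        eucl = np.linalg.norm(lib.features - q, axis=1)
        brute = np.lexsort((np.arange(len(eucl)), eucl))[:10]
        np.testing.assert_array_equal(idx, brute)

    def test_exact_match_distance_zero(self, rng):
        lib = make_library(rng)
        idx, d = mahalanobis_select(lib.features[17], lib, 1)
        assert idx[0] == 17
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_top_k_matches_brute_force_full_sort(self, rng):
        lib = make_library(rng, n=200)
        q = np.array([0.3, -0.5])
        idx, _ = mahalanobis_select(q, lib, 80)
        sinv = np.linalg.inv(lib.cov)
        diff = lib.features - q
        full = np.sqrt(np.einsum("ij,jk,ik->i", diff, sinv, diff))
        brute = np.lexsort((np.arange(len(full)), full))[:80]
        np.testing.assert_array_equal(idx, brute)

    def test_singular_covariance_error(self, rng):
        lib = make_library(rng, cov=np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(np.linalg.LinAlgError, match="degenera"):
            mahalanobis_select(np.zeros(2), lib, 5)

    def test_library_smaller_than_k(self, rng):
        lib = make_library(rng, n=10)
        with pytest.raises(ValueError):
            mahalanobis_select(np.zeros(2), lib, 11)


class TestEnsembleWeights:
    def test_symmetric_candidates_uniform(self, flat_hierarchy):
        cand = pd.DataFrame({"location_id": ["B"] * 8, "age": [30.0] * 8,
                             "cohort": [1970.0] * 8})
        w = ensemble_weights(27.0, 1975.0, "A", cand, flat_hierarchy)
        np.testing.assert_allclose(w, 1 / 8, atol=1e-12)

    def test_same_country_beats_other_super_region(self, flat_hierarchy):
        cfg = EnsembleConfig()
        cand = pd.DataFrame({"location_id": ["A", "D"], "age": [30.0, 30.0],
                             "cohort": [1970.0, 1970.0]})
        w = ensemble_weights(27.0, 1975.0, "A", cand, flat_hierarchy, cfg)
        assert w[0] > w[1]
        # hand computation from the printed constants: equal age/cohort
        # distances rescale to the floor 0.001 for both candidates
        base = (cfg.p_age * 0.001) ** cfg.psi + (cfg.p_cohort * 0.001) ** cfg.psi
        d_same = base + (cfg.p_space * 0.001) ** cfg.psi
        d_other = base + (cfg.p_space * 1.0) ** cfg.psi
        expected_ratio = (1 / d_same) / (1 / d_other)
        assert w[0] / w[1] == pytest.approx(expected_ratio, rel=1e-9)

    def test_weights_sum_to_one(self, flat_hierarchy, rng):
        for _ in range(10):
            n = int(rng.integers(2, 30))
            cand = pd.DataFrame({
                "location_id": rng.choice(["A", "B", "C", "D"], n),
                "age": rng.uniform(25, 60, n),
                "cohort": rng.uniform(1940, 1995, n)})
            w = ensemble_weights(30.0, 1980.0, "B", cand, flat_hierarchy)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestEnsembleAverage:
    def test_identical_candidates(self, rng):
        d = random_distribution(rng)
        out = ensemble_average(np.tile(d, (5, 1)), np.full(5, 0.2))
        np.testing.assert_allclose(out, d, atol=1e-15)

    def test_two_point_masses(self):
        bins = np.zeros((2, 19))
        bins[0, 6] = 1.0
        bins[1, 12] = 1.0
        out = ensemble_average(bins, np.array([0.5, 0.5]))
        assert out[6] == 0.5 and out[12] == 0.5

    def test_matches_loop_oracle(self, rng):
        bins = random_distribution(rng, n=12)
        w = rng.uniform(0.1, 1.0, 12)
        w = w / w.sum()
        out = ensemble_average(bins, w)
        brute = np.zeros(19)
        for i in range(12):
            for b in range(19):
                brute[b] += w[i] * bins[i, b]
        np.testing.assert_allclose(out, brute, atol=1e-14)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_weights_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_average(random_distribution(rng, n=3), np.array([1.0, 1.0, 1.0]))


class TestLoess:
    YEARS = np.arange(1970, 2019, dtype=float)

    def test_constant_series_unchanged(self, rng):
        d = random_distribution(rng)
        series = np.tile(d, (len(self.YEARS), 1))
        out = loess_smooth_bins(self.YEARS, series, 0.5)
        np.testing.assert_allclose(out, series, atol=1e-9)

    def test_spike_amplitude_reduced(self, rng):
        d = random_distribution(rng)
        series = np.tile(d, (len(self.YEARS), 1))
        spike_year = 25
        series[spike_year, 3] += 0.3
        series[spike_year] /= series[spike_year].sum()
        out = loess_smooth_bins(self.YEARS, series, 0.5)
        assert out[spike_year, 3] < series[spike_year, 3]

    def test_rows_renormalized(self, rng):
        series = random_distribution(rng, n=len(self.YEARS))
        out = loess_smooth_bins(self.YEARS, series, 0.5)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()

    def test_short_series_pass_through(self, rng):
        series = random_distribution(rng, n=3)
        with pytest.warns(UserWarning):
            out = loess_smooth_bins(np.arange(3.0), series, 0.5)
        np.testing.assert_array_equal(out, series)


class TestLibrary:
    def test_build_from_observations(self, rng):
        bins = random_distribution(rng, n=6)
        df = pd.DataFrame({
            "location_id": ["A"] * 6, "provider": "p", "year": 2000,
            "sex": "male", "age_lo": 25, "age_hi": 29, "n_eff": 100.0,
            **{f"p{k}": bins[:, k] for k in range(19)}})
        lib = build_library(df)
        assert len(lib) == 6
        np.testing.assert_allclose(lib.meta["cohort"], 2000 - 27.0)
        assert lib.cov.shape == (2, 2)

    def test_invariants_enforced(self, rng):
        bins = random_distribution(rng, n=4)
        bins[0] *= 2  # break normalization
        with pytest.raises(ValueError):
            CandidateLibrary(features=np.zeros((4, 2)), bins=bins,
                             meta=pd.DataFrame(index=range(4)))


def mixture_library(rng, n):
    from edudist.synthetic import mixture_distribution

    bins = np.vstack([
        mixture_distribution(m, min(p0, 1 - m / 17.9), s)
        for m, p0, s in zip(rng.uniform(1.5, 16.0, n),
                            rng.uniform(0.01, 0.5, n),
                            rng.uniform(0.8, 1.5, n))])
    means = bins @ BIN_YEARS
    features = np.column_stack([logit(means / 18.0), logit(bins[:, 0])])
    meta = pd.DataFrame({
        "location_id": rng.choice(["A", "B", "C", "D"], n),
        "age": rng.choice([27.0, 32.0, 37.0], n),
        "cohort": rng.integers(1940, 1995, n).astype(float),
        "provider": "prov"})
    return CandidateLibrary(features=features, bins=bins, meta=meta)


def test_reconstruction_recovers_query_features(flat_hierarchy, rng):
    """End-to-end: reconstructed distributions reproduce query features
    when the library contains the truth family."""
    lib = mixture_library(rng, 800)
    pick = rng.choice(len(lib), 10, replace=False)
    q = lib.features[pick] + rng.normal(0, 0.02, (10, 2))
    out = reconstruct_series(q, np.arange(2000, 2010), 30.0, "A", lib,
                             flat_hierarchy, EnsembleConfig(k=20), smooth=False)
    means = out @ BIN_YEARS
    err_mean = np.abs(logit(means / 18.0) - q[:, 0])
    err_p0 = np.abs(logit(out[:, 0]) - q[:, 1])
    assert err_mean.mean() < 0.15
    assert err_p0.mean() < 0.15


def test_reconstruction_total_variation_vs_truth(small_world, rng):
    """Synthetic recovery: with the truth family in a ~2,000-entry library,
    reconstructed shapes are close to truth in total variation."""
    from edudist.synthetic import ProviderSpec, observations_to_frame, simulate_survey
    from edudist.synthetic import truth_summary

    hierarchy, truth = small_world
    obs = []
    for loc in hierarchy.countries:
        spec = ProviderSpec(name="census", years=tuple(range(1995, 2019, 3)),
                            locations=(loc,), no_noise=True)
        obs.extend(simulate_survey(truth, spec, seed=1, ages=range(25, 46, 2)))
    lib = build_library(observations_to_frame(obs))
    assert len(lib) >= 2000
    tvs = []
    for _ in range(30):
        loc = hierarchy.countries[int(rng.integers(len(hierarchy.countries)))]
        year = int(rng.integers(1996, 2018))
        sex = ("male", "female")[int(rng.integers(2))]
        tr = truth_summary(truth, loc, 30, sex, year)
        q = np.array([[float(logit((tr @ BIN_YEARS) / 18.0)), float(logit(tr[0]))]])
        out = reconstruct_series(q, np.array([year]), 30.0, loc, lib, hierarchy,
                                 EnsembleConfig(k=20), smooth=False)
        tvs.append(0.5 * np.abs(out[0] - tr).sum())
    assert np.mean(tvs) < 0.05
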