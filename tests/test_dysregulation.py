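"""Reference-population fitting and Mahalanobis dysregulation scores."""

import math

import numpy as np
import pandas as pd
import pytest

from dsign import (
    Cohort,
    CompositeRPConfig,
    ReferencePopulation,
    TransformSpec,
    build_composite_rp,
    compute_dm,
    fit_reference,
    score_per_sd,
)
from dsign.errors import CalibrationError, InsufficientDataError, ScalingError, SizeError
from tests.conftest import random_pd_cov


def _cohort_from_matrix(X, names, label="c"):
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=names)
    df.insert(0, "subject_id", [f"{label}{i}" for i in range(len(df))])
    df.insert(1, "age", 50.0 + np.arange(len(df)))
    return Cohort(label, df, names)


def _manual_rp(mu, sigma, names, n=1000):
    """RP with identity transforms and unit standardization: scores raw values."""
    p = len(names)
    return ReferencePopulation(
        set_label="manual",
        biomarker_names=names,
        transform_spec=TransformSpec.identity(names),
        standardize_mean=np.zeros(p),
        standardize_sd=np.ones(p),
        mu=np.asarray(mu, dtype=float),
        sigma=np.asarray(sigma, dtype=float),
        n_reference=n,
    )


class TestFitReference:
    def test_hand_computable_two_marker_fit(self, identity_spec):
        cohort = _cohort_from_matrix([[0, 0], [2, 0], [0, 2], [2, 2]], ["a", "b"])
        rp = fit_reference(cohort, ["a", "b"], transform_spec=identity_spec(["a", "b"]))
        np.testing.assert_allclose(rp.standardize_mean, [1.0, 1.0])
        np.testing.assert_allclose(rp.standardize_sd, [math.sqrt(4 / 3)] * 2)
        np.testing.assert_allclose(rp.mu, [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(rp.sigma, np.eye(2), atol=1e-12)
        assert rp.n_reference == 4

    def test_collinear_markers_rejected(self, identity_spec):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        cohort = _cohort_from_matrix(np.column_stack([a, 2 * a]), ["a", "b"])
        with pytest.raises(CalibrationError, match="collinear"):
            fit_reference(cohort, ["a", "b"], transform_spec=identity_spec(["a", "b"]))

    def test_too_few_rows_rejected(self, identity_spec):
        cohort = _cohort_from_matrix(np.random.default_rng(1).normal(size=(3, 2)), ["a", "b"])
        with pytest.raises(InsufficientDataError):
            fit_reference(cohort, ["a", "b"], transform_spec=identity_spec(["a", "b"]))


@pytest.fixture(scope="module")
def sources(mvn_cohort):
    return [mvn_cohort(10, 2, seed=s, label=f"s{s}", marker_names=["a", "b"]) for s in (1, 2)]


class TestCompositeRP:
    def test_equal_allocation(self, sources, identity_spec):
        cfg = CompositeRPConfig(sources=sources, n_per_source=5, seed=9)
        composite, rp = build_composite_rp(cfg, ["a", "b"], transform_spec=identity_spec(["a", "b"]))
        assert len(composite) == 10
        assert composite.data["dataset_label"].value_counts().tolist() == [5, 5]
        assert rp.provenance["kind"] == "composite"

    def test_same_seed_same_selection(self, sources, identity_spec):
        spec = identity_spec(["a", "b"])
        cfg = CompositeRPConfig(sources=sources, n_per_source=5, seed=9)
        _, rp1 = build_composite_rp(cfg, ["a", "b"], transform_spec=spec)
        _, rp2 = build_composite_rp(cfg, ["a", "b"], transform_spec=spec)
        assert rp1.provenance["sampled_subject_ids"] == rp2.provenance["sampled_subject_ids"]
        np.testing.assert_array_equal(rp1.sigma, rp2.sigma)

    def test_identical_sources_match_single_source_fit(self, mvn_cohort, identity_spec):
        base = mvn_cohort(40, 3, seed=3, marker_names=["a", "b", "c"])
        spec = identity_spec(["a", "b", "c"])
        clones = []
        for k in range(3):
            df = base.data.copy()
            df["subject_id"] = df["subject_id"] + f"_{k}"
            clones.append(Cohort(f"clone{k}", df, ["a", "b", "c"]))
        cfg = CompositeRPConfig(sources=clones, n_per_source=40, seed=0)
        _, rp = build_composite_rp(cfg, ["a", "b", "c"], transform_spec=spec)
        single = fit_reference(base, ["a", "b", "c"], transform_spec=spec)
        # oracle: pooling three identical copies shifts nothing but the
        # covariance denominator (3n-1 vs n-1); rescale to compare
        np.testing.assert_allclose(rp.standardize_mean, single.standardize_mean, atol=1e-12)
        np.testing.assert_allclose(rp.mu, single.mu, atol=1e-12)
        # standardizing by the sample's own SDs makes sigma the sample
        # correlation matrix, so it is identical for pooled copies
        np.testing.assert_allclose(rp.sigma, single.sigma, atol=1e-12)
        scale = (3 * 40 - 1) / (3 * 40) * (40 / (40 - 1))
        np.testing.assert_allclose(
            rp.standardize_sd**2 * scale, single.standardize_sd**2, rtol=1e-10
        )

    def test_oversized_request_names_source(self, sources, identity_spec):
        cfg = CompositeRPConfig(sources=sources, n_per_source=11, seed=0)
        with pytest.raises(SizeError, match="s1"):
            build_composite_rp(cfg, ["a", "b"], transform_spec=identity_spec(["a", "b"]))


class TestComputeDM:
    def test_centroid_scores_zero_and_log_flagged(self):
        rp = _manual_rp([0.0, 0.0], np.eye(2), ["a", "b"])
        cohort = _cohort_from_matrix([[0.0, 0.0]], ["a", "b"])
        res = compute_dm(cohort, rp)
        assert res.dm.iloc[0] == 0.0
        assert np.isnan(res.log_dm.iloc[0])
        assert res.n_zero_dm == 1

    def test_unit_displacement_under_identity_covariance(self):
        p = 9
        names = [f"m{j}" for j in range(p)]
        rp = _manual_rp(np.zeros(p), np.eye(p), names)
        x = np.zeros((1, p))
        x[0, 0] = 1.0
        res = compute_dm(_cohort_from_matrix(x, names), rp)
        assert math.isclose(res.dm.iloc[0], 1.0, rel_tol=1e-12)

    def test_correlated_two_marker_oracle(self):
        # explicit 2x2 inverse of [[1,.5],[.5,1]] is [[4/3,-2/3],[-2/3,4/3]]
        rp = _manual_rp([0.0, 0.0], [[1.0, 0.5], [0.5, 1.0]], ["a", "b"])
        res = compute_dm(_cohort_from_matrix([[1.0, 1.0]], ["a", "b"]), rp)
        assert math.isclose(res.dm.iloc[0], math.sqrt(4 / 3), rel_tol=1e-12)

    def test_matches_explicit_inverse_on_random_instances(self, mvn_cohort, identity_spec):
        rng = np.random.default_rng(99)
        for p in (2, 9, 17):
            names = [f"m{j}" for j in range(p)]
            cov = random_pd_cov(p, rng)
            fit = mvn_cohort(300, p, seed=int(rng.integers(2**31)), cov=cov, label="fit")
            score = mvn_cohort(200, p, seed=int(rng.integers(2**31)), cov=cov, label="sc")
            rp = fit_reference(fit, names, transform_spec=identity_spec(names))
            res = compute_dm(score, rp)
            Z = (score.data[names].to_numpy(dtype=float) - rp.standardize_mean) / rp.standardize_sd
            D = Z - rp.mu
            oracle = np.sqrt(np.einsum("ij,ij->i", D @ np.linalg.inv(rp.sigma), D))
            np.testing.assert_allclose(res.dm.to_numpy(), oracle, atol=1e-10)

    def test_missing_rows_excluded_and_counted(self):
        rp = _manual_rp([0.0, 0.0], np.eye(2), ["a", "b"])
        cohort = _cohort_from_matrix([[1.0, 1.0], [np.nan, 0.0]], ["a", "b"])
        res = compute_dm(cohort, rp)
        assert len(res.scores) == 1
        assert res.n_excluded == 1

    def test_monotone_along_a_ray(self):
        rng = np.random.default_rng(5)
        p = 4
        names = [f"m{j}" for j in range(p)]
        sigma = random_pd_cov(p, rng)
        rp = _manual_rp(np.zeros(p), sigma, names)
        v = rng.standard_normal(p)
        ts = np.linspace(0.1, 3.0, 12)
        X = np.outer(ts, v)
        res = compute_dm(_cohort_from_matrix(X, names), rp)
        assert np.all(np.diff(res.dm.to_numpy()) > 0)

    def test_self_rp_moment_identity(self, mvn_cohort, identity_spec):
        n, p = 500, 9
        names = [f"m{j}" for j in range(p)]
        cohort = mvn_cohort(n, p, seed=17, cov=random_pd_cov(p, np.random.default_rng(4)))
        rp = fit_reference(cohort, names, transform_spec=identity_spec(names))
        res = compute_dm(cohort, rp)
        assert math.isclose((res.dm**2).mean(), p * (n - 1) / n, abs_tol=1e-8)

    def test_affine_invariance(self, mvn_cohort, identity_spec):
        p = 5
        names = [f"m{j}" for j in range(p)]
        fit = mvn_cohort(300, p, seed=21, label="fit")
        score = mvn_cohort(150, p, seed=22, label="sc")
        spec = identity_spec(names)
        base = compute_dm(score, fit_reference(fit, names, transform_spec=spec)).dm.to_numpy()
        fit2, score2 = fit.data.copy(), score.data.copy()
        for j, name in enumerate(names):  # rescale every column differently
            c, b = 3.5 + j, -7.0 + 2 * j
            fit2[name] = c * fit2[name] + b
            score2[name] = c * score2[name] + b
        rp2 = fit_reference(Cohort("fit2", fit2, names), names, transform_spec=spec)
        scaled = compute_dm(Cohort("sc2", score2, names), rp2).dm.to_numpy()
        np.testing.assert_allclose(scaled, base, atol=1e-8)


class TestScorePerSD:
    def test_definition(self):
        out = score_per_sd([2.0, 4.0])
        np.testing.assert_allclose(out, [math.sqrt(2), 2 * math.sqrt(2)])

    def test_output_sd_is_one(self):
        rng = np.random.default_rng(2)
        out = score_per_sd(rng.normal(5, 3, size=100))
        assert abs(np.std(out, ddof=1) - 1.0) < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ScalingError):
            score_per_sd([1.0, 1.0, 1.0])

    def test_nan_passthrough(self):
        out = score_per_sd([1.0, np.nan, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[0])
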