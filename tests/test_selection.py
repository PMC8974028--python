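"""Biomarker pre-selection, subset enumeration, and stability matrices."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from dsign import (
    DM9_NAMES,
    Cohort,
    CompositeRPConfig,
    SyntheticConfig,
    cross_rp_stability,
    enumerate_and_evaluate,
    generate_cohorts,
    generate_rp_pair,
    pre_select,
    redundancy_report,
    subset_stability,
)
from dsign.errors import ConfigurationError, InsufficientDataError
from dsign.panel import BiomarkerDef, BiomarkerPanel
from dsign.selection import _combination_from_rank

MARKERS9 = list(DM9_NAMES)


def _cfg(**kw):
    kw.setdefault("marker_names", MARKERS9)
    kw.setdefault("include_al_components", False)
    kw.setdefault("simulate_outcomes", False)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="module")
def triple():
    return generate_cohorts(_cfg(n_per_dataset=(1000, 1000, 1000), seed=100))


class TestPreSelect:
    def test_identical_generating_process_keeps_all(self, triple):
        retained, report = pre_select(triple, threshold_d=0.5)
        assert sorted(retained) == sorted(MARKERS9)
        assert not report["excluded"].any()

    def test_planted_shift_excluded_others_kept(self):
        cohorts = generate_cohorts(
            _cfg(
                n_per_dataset=(1000, 1000, 1000),
                seed=101,
                dataset_shifts={"cohort_2": {"hdl": 2.0}},
            )
        )
        retained, report = pre_select(cohorts, threshold_d=0.5)
        assert "hdl" not in retained
        assert sorted(retained) == sorted(set(MARKERS9) - {"hdl"})
        # oracle: the empirical standardized difference is ~2 by construction
        stat = report.loc[
            (report.biomarker == "hdl") & (report.subset == "all"), "max_std_diff"
        ].iloc[0]
        assert abs(stat - 2.0) < 0.3

    def test_clinical_bounds_rule(self, triple):
        panel = BiomarkerPanel(
            [BiomarkerDef(m, clinical_low=10.0, clinical_high=100.0) if m == "hdl"
             else BiomarkerDef(m) for m in MARKERS9]
        )
        shifted = []
        for c in triple:
            df = c.data.copy()
            df["hdl"] = df["hdl"] + 200.0
            shifted.append(Cohort(c.dataset_label, df, MARKERS9))
        retained, report = pre_select(shifted, panel=panel, use_clinical_bounds=True)
        assert "hdl" not in retained
        reason = report.loc[report.biomarker == "hdl", "reason"].iloc[0]
        assert "clinical bounds" in reason

    def test_missing_split_variable_rejected(self, triple):
        with pytest.raises(ConfigurationError, match="nonexistent"):
            pre_select(triple, subset_vars=["nonexistent"])

    def test_needs_two_cohorts(self, triple):
        with pytest.raises(ConfigurationError):
            pre_select(triple[:1])


@pytest.fixture(scope="module")
def pair():
    return generate_cohorts(_cfg(n_per_dataset=(400, 400), seed=102))


class TestEnumeration:
    def test_counting_and_order(self, pair):
        cand = MARKERS9[:5]
        cfg = CompositeRPConfig(sources=list(pair), n_per_source=300, seed=1)
        evals = enumerate_and_evaluate(pair, cand, 2, cfg, MARKERS9)
        assert len(evals) == math.comb(5, 2) == 10
        key = [(e.mean_rp_stability, e.mean_signal) for e in evals if not e.failed]
        assert key == sorted(key, key=lambda t: (-t[0], -t[1]))

    def test_full_set_has_unit_signal(self, pair):
        cfg = CompositeRPConfig(sources=list(pair), n_per_source=300, seed=1)
        evals = enumerate_and_evaluate(pair, MARKERS9, 9, cfg, MARKERS9)
        assert len(evals) == 1
        for r in evals[0].signal_r.values():
            assert math.isclose(r, 1.0, abs_tol=1e-9)

    def test_single_source_composite_is_own_rp(self, pair):
        c = pair[0]
        cfg = CompositeRPConfig(
            sources=[c], n_per_source=len(c.complete_cases(MARKERS9)), seed=0
        )
        evals = enumerate_and_evaluate([c], MARKERS9[:4], 4, cfg, MARKERS9)
        # the composite RP is fitted on exactly the cohort's own rows
        assert math.isclose(evals[0].rp_stability_r[c.dataset_label], 1.0, abs_tol=1e-9)

    def test_budget_enforced_without_sampling(self, pair):
        cfg = CompositeRPConfig(sources=list(pair), n_per_source=300, seed=1)
        with pytest.raises(ConfigurationError, match="budget"):
            enumerate_and_evaluate(pair, MARKERS9, 4, cfg, MARKERS9, budget=10)

    def test_seeded_sampling_deterministic(self, pair):
        cfg = CompositeRPConfig(sources=list(pair), n_per_source=300, seed=1)
        kw = dict(sample=(5, 7), budget=10)
        e1 = enumerate_and_evaluate(pair, MARKERS9, 4, cfg, MARKERS9, **kw)
        e2 = enumerate_and_evaluate(pair, MARKERS9, 4, cfg, MARKERS9, **kw)
        assert [e.biomarker_names for e in e1] == [e.biomarker_names for e in e2]
        assert [e.mean_rp_stability for e in e1] == [e.mean_rp_stability for e in e2]

    def test_combination_unranking_matches_lexicographic(self):
        n, k = 7, 3
        expected = list(combinations(range(n), k))
        got = [_combination_from_rank(r, n, k) for r in range(math.comb(n, k))]
        assert got == expected


class TestCrossRPStability:
    def test_identical_cohorts_give_unit_matrix(self, mvn_cohort):
        a = mvn_cohort(200, 3, seed=31, label="A", marker_names=["x", "y", "z"])
        b = Cohort("B", a.data.copy(), ["x", "y", "z"])
        m = cross_rp_stability([a, b], ["x", "y", "z"])
        np.testing.assert_allclose(m.r, 1.0, atol=1e-12)

    def test_same_distribution_high_mean_r(self):
        a, b = generate_rp_pair(_cfg(n_per_dataset=(2000,), seed=103))
        m = cross_rp_stability([a, b], MARKERS9)
        assert m.mean_r >= 0.99
        assert np.allclose(np.diag(m.r[: len(m.col_labels)]), 1.0, atol=1e-12)

    def test_perturbation_lowers_mean_r(self):
        cfg = _cfg(n_per_dataset=(2000,), seed=103)
        a0, b0 = generate_rp_pair(cfg)
        base = cross_rp_stability([a0, b0], MARKERS9).mean_r
        a1, b1 = generate_rp_pair(
            cfg,
            perturbation={"shift_sd": 3.0, "markers": MARKERS9[:4], "var_multiplier": 2.0},
        )
        perturbed = cross_rp_stability([a1, b1], MARKERS9).mean_r
        assert perturbed < base

    def test_pooled_row_optional(self):
        a, b = generate_rp_pair(_cfg(n_per_dataset=(500,), seed=104))
        m = cross_rp_stability([a, b], MARKERS9, include_pooled=True)
        assert m.row_labels[-1] == "pooled"
        assert m.r.shape == (3, 2)
        assert np.isfinite(m.mean_r)


class TestSubsetStability:
    def test_constant_split_rejected(self):
        (c,) = generate_cohorts(_cfg(n_per_dataset=(300,), seed=105))
        c.data["const"] = "same"
        with pytest.raises(InsufficientDataError):
            subset_stability(c, MARKERS9, "const")

    def test_random_split_of_homogeneous_cohort_is_stable(self):
        (c,) = generate_cohorts(_cfg(n_per_dataset=(4000,), seed=106))
        rng = np.random.default_rng(0)
        c.data["half"] = np.where(rng.random(len(c)) < 0.5, "g1", "g2")
        m = subset_stability(c, MARKERS9, "half")
        assert m.mean_r >= 0.99

    def test_split_indexing_planted_shift_is_less_stable(self):
        cfg = _cfg(n_per_dataset=(2000, 2000), seed=107,
                   dataset_shifts={"cohort_2": {m: 2.0 for m in MARKERS9[:4]}})
        a, b = generate_cohorts(cfg)
        merged = pd.concat(
            [a.data.assign(grp="A", subject_id="A" + a.data.subject_id),
             b.data.assign(grp="B", subject_id="B" + b.data.subject_id)],
            ignore_index=True,
        )
        c = Cohort("merged", merged, MARKERS9)
        rng = np.random.default_rng(1)
        c.data["rand"] = np.where(rng.random(len(c)) < 0.5, "g1", "g2")
        shifted = subset_stability(c, MARKERS9, "grp").mean_r
        random_split = subset_stability(c, MARKERS9, "rand").mean_r
        assert shifted < random_split


class TestRedundancy:
    def test_duplicated_marker_flagged_and_diag_one(self, mvn_cohort):
        c = mvn_cohort(100, 2, seed=41, marker_names=["a", "b"])
        c.data["a_copy"] = c.data["a"]
        cc = Cohort("dup", c.data, ["a", "b", "a_copy"])
        rep = redundancy_report(cc, ["a", "b", "a_copy"])
        assert np.allclose(np.diag(rep.correlations.to_numpy()), 1.0)
        assert ("a", "a_copy", 1.0) in [(x, y, round(r, 6)) for x, y, r in rep.flagged]

    def test_independent_markers_unflagged(self, mvn_cohort):
        c = mvn_cohort(2000, 5, seed=42, marker_names=list("abcde"))
        rep = redundancy_report(c, list("abcde"))
        off = rep.correlations.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert rep.flagged == []

    def test_needs_thirty_complete_cases(self, mvn_cohort):
        c = mvn_cohort(20, 2, seed=43, marker_names=["a", "b"])
        with pytest.raises(InsufficientDataError):
            redundancy_report(c, ["a", "b"])
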