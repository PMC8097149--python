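"""Statistical layer: exact Mann-Whitney, Pearson, Bonferroni, reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vrsquant.stats import (
    bonferroni_threshold,
    build_report,
    mann_whitney_u,
    pearson_r,
)


def mw_enumeration_oracle(x, y):
    """Independent exact two-sided Mann-Whitney by full rank enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(n + m)
    ranks[order] = np.arange(1, n + m + 1)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [sum(c) - n * (n + 1) / 2 for c in itertools.combinations(range(1, n + m + 1), n)]
    )
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_complete_separation_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 assignments are as extreme

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_oracle_many_datasets(self):
        """Exact p equals full enumeration for min(n, m) <= 6, 50 datasets."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 9))
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=m)
            u0, p0 = mw_enumeration_oracle(x, y)
            u1, p1 = mann_whitney_u(x, y)
            assert u1 == pytest.approx(u0)
            assert p1 == pytest.approx(p0, abs=1e-12)

    def test_symmetry_under_sample_swap(self):
        rng = np.random.default_rng(1)
        for size in ((4, 9), (15, 20)):
            x, y = rng.normal(size=size[0]), rng.normal(0.5, size=size[1])
            assert mann_whitney_u(x, y)[1] == pytest.approx(mann_whitney_u(y, x)[1])

    def test_separation_at_study_burden_parameters(self):
        """Epilepsy vs control VRS counts (n=33 vs 28) separate at p < .001."""
        import dataclasses

        from vrsquant.cohort import default_config, sample_cohort

        cfg = default_config()
        hits = 0
        for seed in range(100):
            recs = sample_cohort(cfg, seed)
            epi = [r.planted_count for r in recs if r.group == "epilepsy"]
            ctl = [r.planted_count for r in recs if r.group == "control"]
            if mann_whitney_u(epi, ctl)[1] < 0.001:
                hits += 1
        assert hits >= 99


class TestPearson:
    def test_collinear_points_r_one(self):
        res = pearson_r([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_symmetric_pattern_r_zero(self):
        assert pearson_r([0, 1, 2], [0, 1, 0]).r == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_t_transform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = pearson_r(x, y)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        p_manual = 2 * sps.t.sf(abs(t), res.n - 2)
        assert res.p == pytest.approx(p_manual, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance_and_sign_flip(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12) + 0.4 * x
        r0 = pearson_r(x, y).r
        assert pearson_r(a * x + b, y).r == pytest.approx(r0, abs=1e-9)
        assert pearson_r(-x, y).r == pytest.approx(-r0, abs=1e-9)

    def test_generator_coupling_recovered_at_large_n(self):
        import dataclasses

        from vrsquant.cohort import default_config, sample_cohort

        cfg = default_config()
        g = dataclasses.replace(cfg.groups["epilepsy"], n=500)
        cfg = dataclasses.replace(cfg, groups={"epilepsy": g})
        recs = sample_cohort(cfg, seed=9)
        d = [r.seizure_duration_min for r in recs]
        k = [float(r.planted_count) for r in recs]
        res = pearson_r(d, k)
        # within the n=500 sampling CI of the configured coupling
        se = (1 - 0.766**2) / np.sqrt(500 - 3)
        assert abs(res.r - 0.766) < 3 * se + 0.03


class TestBonferroni:
    def test_three_comparisons_rounds_to_017(self):
        exact, rounded = bonferroni_threshold(0.05, 3)
        assert exact == pytest.approx(0.05 / 3)
        assert rounded == 0.017

    def test_single_comparison_identity(self):
        assert bonferroni_threshold(0.05, 1) == (0.05, 0.05)

    def test_arithmetic(self):
        assert bonferroni_threshold(0.03, 3)[0] == pytest.approx(0.01)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _toy_frame(rng, n=8):
    rows = []
    for g, shift in (("SFS", 40.0), ("epilepsy", 120.0), ("control", 0.0)):
        for i in range(n):
            seizure = g != "control"
            rows.append(
                {
                    "subject_id": f"{g}_{i}",
                    "group": g,
                    "vrs_count": 350 + shift + rng.normal(0, 20),
                    "vrs_volume_mm3": 4000 + 30 * shift + rng.normal(0, 300),
                    "wm_volume_mm3": 3.1e5 + rng.normal(0, 1e4),
                    "brain_volume_mm3": 9e5 + rng.normal(0, 2e4),
                    "seizure_duration_min": rng.uniform(1, 10) if seizure else np.nan,
                    "course_days": rng.uniform(1, 7) if seizure else np.nan,
                }
            )
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_structure_twelve_pairwise_pvalues(self):
        report = build_report(_toy_frame(np.random.default_rng(0)))
        assert len(report.comparisons) == 4
        total_p = sum(len(c.pairwise_p) for c in report.comparisons)
        assert total_p == 12
        assert report.threshold_rounded == 0.017

    def test_group_means_match_direct_recomputation(self):
        df = _toy_frame(np.random.default_rng(1))
        report = build_report(df)
        for comp in report.comparisons:
            for g, (mean, sd) in comp.group_stats.items():
                vals = df.loc[df.group == g, comp.metric]
                assert mean == pytest.approx(vals.mean())
                assert sd == pytest.approx(vals.std(ddof=1))

    def test_controls_carry_no_correlations(self):
        report = build_report(_toy_frame(np.random.default_rng(2)))
        groups_with_corr = {c.pair[0].split(":")[0] for c in report.correlations}
        assert groups_with_corr == {"SFS", "epilepsy"}
        # 2 groups x 2 covariates x 2 metrics
        assert len(report.correlations) == 8

    def test_missing_covariates_error_names_subjects(self):
        df = _toy_frame(np.random.default_rng(3))
        df.loc[df.subject_id == "SFS_2", "seizure_duration_min"] = np.nan
        with pytest.raises(ValueError, match="SFS_2"):
            build_report(df)

    def test_significance_flags_respect_threshold(self):
        report = build_report(_toy_frame(np.random.default_rng(4)))
        for comp in report.comparisons:
            for pair, p in comp.pairwise_p.items():
                assert comp.significant[pair] == (p < report.threshold_exact)

    def test_too_few_groups_rejected(self):
        df = _toy_frame(np.random.default_rng(5))
        with pytest.raises(ValueError):
            build_report(df[df.group == "SFS"])
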