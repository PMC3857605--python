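import numpy as np
import pytest

from conneff.records import EfficiencyTable, SubjectRecord
from conneff.stats import (
    cosine_similarity,
    fdr_adjust,
    fit_region_models,
)


def make_table(values, region_ids=None):
    """Wrap an (n_subjects, n_regions) array as an EfficiencyTable."""
    values = np.asarray(values, dtype=float)
    n_sub, n_reg = values.shape
    rids = np.arange(1, n_reg + 1) if region_ids is None else region_ids
    return EfficiencyTable(
        subject_ids=[f"s{i:02d}" for i in range(n_sub)],
        region_ids=rids,
        nodal_local=values,
        nodal_global=values,
    )


def make_subjects(icv, age=None, tbv=None, group=None):
    icv = np.asarray(icv, dtype=float)
    n = icv.size
    age = np.full(n, 30.0) + np.arange(n) if age is None else np.asarray(age, float)
    tbv = 0.8 * icv if tbv is None else np.asarray(tbv, float)
    group = ["control"] * n if group is None else list(group)
    return [
        SubjectRecord(f"s{i:02d}", group[i], float(age[i]), float(icv[i]), float(tbv[i]))
        for i in range(n)
    ]


class TestFitRegionModels:
    def test_noise_free_slope_recovered_exactly(self, rng):
        n = 12
        icv = 1.4e6 + 2e4 * np.arange(n)
        age = rng.uniform(20, 50, n)
        tbv = 0.8 * icv + rng.normal(0, 1e3, n)  # not collinear with icv
        b = 3.0e-8
        eff = 0.9 - b * icv
        subjects = make_subjects(icv, age=age, tbv=tbv)
        res = fit_region_models(
            make_table(np.column_stack([eff, eff])), subjects, "icv", "local"
        )
        for r in res:
            assert r.beta == pytest.approx(-b, rel=1e-8)
            assert abs(r.t) > 1e5  # zero-residual fit
            assert r.p < 1e-12

    def test_slope_matches_hand_projection_on_orthogonal_design(self):
        # covariates constructed orthogonal to icv (and to each other), so the
        # multivariate icv coefficient equals the simple-regression slope
        # S_xy / S_xx computed by hand
        n = 8
        x = np.array([-7.0, -5.0, -3.0, -1.0, 1.0, 3.0, 5.0, 7.0])
        q, _ = np.linalg.qr(
            np.column_stack([np.ones(n), x, np.arange(n) ** 2, np.arange(n) ** 3])
        )
        age_dev, tbv_dev = q[:, 2], q[:, 3]  # orthogonal to 1 and x
        icv = 1.5e6 + 1e4 * x
        age = 35.0 + 5.0 * age_dev
        tbv = 1.2e6 + 1e4 * tbv_dev
        y = 0.5 + 2.0e-8 * (icv - 1.5e6) + np.array(
            [0.003, -0.003, 0.002, -0.002, 0.001, -0.001, 0.0, 0.0]
        )
        subjects = make_subjects(icv, age=age, tbv=tbv)
        res = fit_region_models(make_table(y[:, None]), subjects, "icv", "local")
        s_xx = np.sum((icv - icv.mean()) ** 2)
        s_xy = np.sum((icv - icv.mean()) * (y - y.mean()))
        assert res[0].beta == pytest.approx(s_xy / s_xx, rel=1e-9)

    def test_matches_statsmodels_on_all_contrasts(self, rng):
        import statsmodels.api as sm

        n, n_reg = 30, 5
        icv = rng.normal(1.5e6, 1e5, n)
        age = rng.uniform(20, 50, n)
        tbv = 0.8 * icv + rng.normal(0, 2e4, n)
        group = ["ASD" if i % 2 else "control" for i in range(n)]
        y = rng.random((n, n_reg))
        subjects = make_subjects(icv, age=age, tbv=tbv, group=group)
        grp = np.array([1.0 if g == "ASD" else 0.0 for g in group])
        designs = {
            "icv": (np.column_stack([np.ones(n), icv, age, tbv]), 1),
            "group": (np.column_stack([np.ones(n), grp, age]), 1),
            "icv_x_group": (
                np.column_stack([np.ones(n), icv, grp, icv * grp, age, tbv]),
                3,
            ),
        }
        for contrast, (x, idx) in designs.items():
            res = fit_region_models(make_table(y), subjects, contrast, "local")
            for r_idx, r in enumerate(res):
                fit = sm.OLS(y[:, r_idx], x).fit()
                assert r.beta == pytest.approx(fit.params[idx], rel=1e-9)
                assert r.t == pytest.approx(fit.tvalues[idx], rel=1e-9)
                assert r.p == pytest.approx(fit.pvalues[idx], rel=1e-9, abs=1e-12)

    def test_t_statistics_invariant_to_covariate_units(self, rng):
        n = 25
        icv = rng.normal(1.5e6, 1e5, n)
        age = rng.uniform(20, 50, n)
        tbv = 0.8 * icv + rng.normal(0, 2e4, n)
        y = rng.random((n, 4))
        t_mm3 = [
            r.t
            for r in fit_region_models(
                make_table(y), make_subjects(icv, age=age, tbv=tbv), "icv", "local"
            )
        ]
        t_cm3 = [
            r.t
            for r in fit_region_models(
                make_table(y),
                make_subjects(icv / 1e3, age=age, tbv=tbv / 1e3),
                "icv",
                "local",
            )
        ]
        np.testing.assert_allclose(t_mm3, t_cm3, atol=1e-9)

    def test_group_coding_makes_asd_reduction_negative(self, rng):
        n = 20
        group = ["ASD"] * 10 + ["control"] * 10
        icv = rng.normal(1.5e6, 1e5, n)
        age = rng.uniform(20, 50, n)
        base = rng.uniform(0.4, 0.6, 6)
        y = np.tile(base, (n, 1)) - 0.1 * np.array(
            [1.0 if g == "ASD" else 0.0 for g in group]
        )[:, None]
        y += rng.normal(0, 1e-4, y.shape)
        res = fit_region_models(
            make_table(y), make_subjects(icv, age=age, group=group), "group", "local"
        )
        assert all(r.t < 0 for r in res)

    def test_null_false_positive_rate_calibrated(self, rng):
        # efficiency independent of all covariates: p < 0.05 in ~5% of regions
        n, n_reg, reps = 44, 78, 200
        hits = total = 0
        for _ in range(reps):
            icv = rng.normal(1.5e6, 1e5, n)
            age = rng.uniform(20, 50, n)
            group = list(rng.permutation(["ASD"] * 22 + ["control"] * 22))
            y = rng.normal(0.5, 0.05, (n, n_reg))
            res = fit_region_models(
                make_table(y), make_subjects(icv, age=age, group=group), "group", "local"
            )
            hits += sum(1 for r in res if r.p < 0.05)
            total += n_reg
        frac = hits / total
        # binomial 99% band around 0.05 for 15600 draws
        assert abs(frac - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / total) + 1e-12

    def test_collinear_design_rejected_with_column_names(self, rng):
        n = 15
        icv = rng.normal(1.5e6, 1e5, n)
        age = rng.uniform(20, 50, n)
        subjects = make_subjects(icv, age=age, tbv=0.5 * icv)  # tbv == c * icv
        with pytest.raises(ValueError, match="collinear"):
            fit_region_models(make_table(rng.random((n, 3))), subjects, "icv", "local")

    def test_missing_subject_covariates_rejected(self, rng):
        subjects = make_subjects(rng.normal(1.5e6, 1e5, 10))
        table = make_table(rng.random((10, 2)))
        table.subject_ids[0] = "unknown"
        with pytest.raises(ValueError, match="unknown"):
            fit_region_models(table, subjects, "icv", "local")

    def test_too_few_subjects_rejected(self, rng):
        subjects = make_subjects(rng.normal(1.5e6, 1e5, 4))
        with pytest.raises(ValueError, match="at least"):
            fit_region_models(make_table(rng.random((4, 2))), subjects, "icv", "local")


class TestFdrAdjust:
    def test_single_p_is_its_own_q(self):
        q, sig = fdr_adjust(np.array([0.04]))
        assert q[0] == pytest.approx(0.04)
        assert sig[0]

    def test_all_ones_stay_ones(self):
        q, sig = fdr_adjust(np.ones(10))
        np.testing.assert_array_equal(q, 1.0)
        assert not sig.any()

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        q, _ = fdr_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_adjust(np.array([0.5, 1.2]))

    def test_invalid_q_level_rejected(self):
        with pytest.raises(ValueError, match="q_level"):
            fdr_adjust(np.array([0.5]), q_level=1.5)


class TestCosineSimilarity:
    def test_identical_vectors(self, rng):
        v = rng.normal(size=10)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1.0 / np.sqrt(2.0)
        )

    def test_scaling_invariance_and_negation_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        base = cosine_similarity(a, b)
        assert cosine_similarity(3.7 * a, b) == pytest.approx(base)
        assert cosine_similarity(a, -b) == pytest.approx(-base)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity(np.zeros(3), np.ones(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            cosine_similarity(np.ones(3), np.ones(4))
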