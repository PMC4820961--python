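"""Value transforms, probe filters, residualization and robust association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methvc import preprocess as pp


def make_matrix(values, scale="m", sites=None, samples=None):
    values = np.atleast_2d(np.asarray(values, float))
    sites = sites or [f"cg{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pp.MethylationMatrix(
        values=pd.DataFrame(values, index=sites, columns=samples), scale=scale
    )


class TestTransforms:
    @pytest.mark.parametrize(
        "M,U,expected",
        [(0, 0, 0.0), (1000, 900, 0.5), (500, 300, 500 / 900)],
    )
    def test_beta_from_intensities(self, M, U, expected):
        assert pp.beta_from_intensities(M, U) == pytest.approx(expected, abs=1e-12)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            pp.beta_from_intensities(-1, 100)

    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.1, np.log2(1 / 9))],
    )
    def test_m_from_beta(self, beta, expected):
        assert pp.m_from_beta(beta) == pytest.approx(expected, abs=1e-12)

    def test_endpoints_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            m = pp.m_from_beta(0.0)
        assert np.isfinite(m)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, beta):
        assert pp.beta_from_m(pp.m_from_beta(beta)) == pytest.approx(beta, abs=1e-12)

    def test_offset_bounds_beta_below_one(self):
        # even a fully methylated probe cannot reach beta = 1 with the offset
        assert pp.beta_from_intensities(1e6, 0) < 1.0


class TestProbeFilters:
    def test_all_pass_is_identity(self):
        meth = make_matrix(np.arange(8).reshape(2, 4))
        out, report = pp.apply_probe_filters(meth, pp.ProbeQcInputs())
        pd.testing.assert_frame_equal(out.values, meth.values)
        assert report.removed_blacklist == 0
        assert report.removed_success_rate == 0

    def test_detection_p_failures_drop_probe_by_success_rate(self):
        # one probe fails detection P in 2 of 4 samples -> success 0.5 < 0.95
        meth = make_matrix(np.ones((2, 4)))
        detp = pd.DataFrame(
            [[0.02, 0.02, 0.001, 0.001], [0.001] * 4],
            index=meth.site_ids, columns=meth.sample_ids,
        )
        out, report = pp.apply_probe_filters(meth, pp.ProbeQcInputs(detection_p=detp))
        assert list(out.site_ids) == ["cg1"]
        assert report.cells_masked_detection_p == 2
        assert report.removed_success_rate == 1

    def test_bead_count_masks_cells(self):
        meth = make_matrix(np.ones((1, 4)))
        beads = pd.DataFrame([[2, 3, 3, 3]], index=meth.site_ids, columns=meth.sample_ids)
        # 1 of 4 failing -> success 0.75 < 0.95 -> dropped
        out, report = pp.apply_probe_filters(meth, pp.ProbeQcInputs(bead_count=beads))
        assert len(out.site_ids) == 0
        assert report.cells_masked_bead_count == 1

    def test_blacklist_removed_regardless_of_qc(self):
        meth = make_matrix(np.ones((2, 4)))
        out, report = pp.apply_probe_filters(
            meth, pp.ProbeQcInputs(blacklist_snp_at_cpg=frozenset({"cg0"}))
        )
        assert list(out.site_ids) == ["cg1"]
        assert report.removed_blacklist == 1

    def test_bad_threshold_rejected(self):
        meth = make_matrix(np.ones((1, 2)))
        with pytest.raises(ValueError):
            pp.apply_probe_filters(meth, pp.ProbeQcInputs(), detp_max=2.0)


class TestContamination:
    @pytest.mark.parametrize(
        "props,expected_count,expected_flag",
        [
            ([0.0, 0.5, 1.0, 0.95], 0, False),
            ([0.3, 0.7] + [0.0] * 63, 2, False),
            ([0.25] * 15 + [0.0] * 50, 15, True),
            ([0.2, 0.4, 0.6, 0.8], 4, False),  # closed interval endpoints
        ],
    )
    def test_counting_rule(self, props, expected_count, expected_flag):
        count, flag = pp.count_unclear_genotypes(props)
        assert count == expected_count
        assert flag is expected_flag

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            pp.count_unclear_genotypes([1.2])


class TestImputation:
    def test_no_missing_identity(self):
        meth = make_matrix([[1.0, 2.0, 3.0]])
        out = pp.impute_missing(meth)
        pd.testing.assert_frame_equal(out.values, meth.values)

    def test_site_mean(self):
        meth = make_matrix([[1.0, 2.0, 3.0, np.nan]])
        out = pp.impute_missing(meth, method="site_mean")
        assert out.values.iloc[0, 3] == pytest.approx(2.0)
        assert out.imputed_mask.iloc[0, 3]

    def test_knn_k_too_large(self):
        meth = make_matrix([[1.0, np.nan], [2.0, 1.0]])
        with pytest.raises(ValueError):
            pp.impute_missing(meth, method="knn", k=10)

    def test_knn_uses_similar_sites(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        X = np.vstack([base + rng.normal(0, 0.01, 20) for _ in range(5)]
                      + [rng.normal(5, 1, 20) for _ in range(5)])
        X[0, 0] = np.nan
        out = pp.impute_missing(make_matrix(X), method="knn", k=3)
        assert out.values.iloc[0, 0] == pytest.approx(base[0], abs=0.2)

    def test_all_missing_site_rejected(self):
        meth = make_matrix([[np.nan, np.nan, 1.0, 1.0]])
        with pytest.raises(ValueError, match="cg0"):
            pp.impute_missing(meth)


class TestResidualize:
    def test_intercept_only_centres(self):
        meth = make_matrix([[1.0, 2.0, 3.0, 6.0]])
        design = pd.DataFrame({"intercept": np.ones(4)},
                              index=meth.sample_ids)
        out, r2 = pp.residualize(meth, design)
        assert out.values.to_numpy().sum() == pytest.approx(0.0, abs=1e-12)
        assert r2.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_site_r2_one(self):
        age = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
        meth = make_matrix([2 * age + 1])
        design = pd.DataFrame({"intercept": np.ones(5), "age": age},
                              index=meth.sample_ids)
        out, r2 = pp.residualize(meth, design)
        assert np.abs(out.values.to_numpy()).max() < 1e-10
        assert r2.iloc[0] == pytest.approx(1.0)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        n = 200
        design = pd.DataFrame(
            {"intercept": np.ones(n), "age": rng.normal(40, 10, n),
             "sex": rng.integers(0, 2, n).astype(float)},
            index=[f"s{i}" for i in range(n)],
        )
        Y = rng.normal(size=(10, n))
        meth = make_matrix(Y, samples=list(design.index))
        out, _ = pp.residualize(meth, design)
        R = out.values.to_numpy()
        X = design.to_numpy()
        Xn = X / np.linalg.norm(X, axis=0)
        Rn = R / np.linalg.norm(R, axis=1, keepdims=True)
        assert np.abs(Rn @ Xn).max() < 1e-8

    def test_injected_covariate_fraction_recovered(self):
        """R2 matches the injected explained-variance fraction over sites."""
        rng = np.random.default_rng(2)
        n, n_sites, target = 500, 60, 0.3
        x = rng.normal(size=n)
        Y = np.sqrt(target) * x + np.sqrt(1 - target) * rng.normal(size=(n_sites, n))
        design = pd.DataFrame({"intercept": np.ones(n), "x": x},
                              index=[f"s{i}" for i in range(n)])
        _, r2 = pp.residualize(make_matrix(Y, samples=list(design.index)), design)
        se = r2.std(ddof=1) / np.sqrt(n_sites)
        assert abs(r2.mean() - target) < 3 * se + 0.01

    def test_variance_shrinks_with_nested_designs(self):
        rng = np.random.default_rng(3)
        n = 100
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = x1 + 0.5 * x2 + rng.normal(size=n)
        meth = make_matrix([y])
        idx = list(meth.sample_ids)
        d1 = pd.DataFrame({"intercept": np.ones(n)}, index=idx)
        d2 = d1.assign(x1=x1)
        d3 = d2.assign(x2=x2)
        variances = [
            pp.residualize(meth, d)[0].values.to_numpy().var() for d in (d1, d2, d3)
        ]
        assert variances[0] >= variances[1] >= variances[2]

    def test_rank_deficient_design_rejected(self):
        n = 10
        design = pd.DataFrame(
            {"intercept": np.ones(n), "a": np.arange(n, dtype=float),
             "b": 2.0 * np.arange(n)},
            index=[f"s{i}" for i in range(n)],
        )
        meth = make_matrix([np.arange(n, dtype=float)], samples=list(design.index))
        with pytest.raises(ValueError, match="collinear"):
            pp.residualize(meth, design)


class TestStandardize:
    def test_mean_zero_sd_one_and_idempotent(self):
        rng = np.random.default_rng(4)
        meth = make_matrix(rng.normal(2, 3, size=(5, 50)))
        z = pp.zstandardize(meth)
        v = z.values.to_numpy()
        assert np.abs(v.mean(axis=1)).max() < 1e-10
        assert np.abs(v.std(axis=1) - 1).max() < 1e-10
        z2 = pp.zstandardize(z)
        assert np.abs(z2.values.to_numpy() - v).max() < 1e-10

    def test_constant_site_rejected(self):
        with pytest.raises(ValueError, match="cg0"):
            pp.zstandardize(make_matrix([[1.0, 1.0, 1.0]]))


class TestRobustAssociation:
    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        n, n_sites = 300, 1000
        fam = pd.Series(np.repeat(np.arange(n // 2), 2), index=[f"s{i}" for i in range(n)])
        x = pd.Series(rng.normal(size=n), index=fam.index)
        Y = rng.normal(size=(n_sites, n))
        meth = make_matrix(Y, samples=list(fam.index))
        res = pp.site_covariate_association(meth, x, fam)
        frac = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_sites)
        assert abs(frac - 0.05) < 3 * se + 0.01

    def test_injected_sex_effect_all_significant(self):
        """A 1-s.d. mean shift at n=500 is detected at genome-wide alpha."""
        rng = np.random.default_rng(6)
        n = 500
        fam = pd.Series(np.repeat(np.arange(n // 2), 2), index=[f"s{i}" for i in range(n)])
        sex = pd.Series(rng.integers(0, 2, n).astype(float), index=fam.index)
        Y = sex.to_numpy() + rng.normal(size=(20, n))
        res = pp.site_covariate_association(make_matrix(Y, samples=list(fam.index)), sex, fam)
        assert (res["p"] < 1.2e-7).all()

    def test_family_correlation_widens_errors(self):
        # fully family-shared noise: cluster-robust se must exceed naive OLS se
        rng = np.random.default_rng(7)
        n = 400
        fam_codes = np.repeat(np.arange(n // 2), 2)
        fam = pd.Series(fam_codes, index=[f"s{i}" for i in range(n)])
        x = pd.Series(rng.normal(size=n // 2)[fam_codes], index=fam.index)  # shared x
        y = rng.normal(size=n // 2)[fam_codes]  # shared noise
        meth = make_matrix([y], samples=list(fam.index))
        res = pp.site_covariate_association(meth, x, fam)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(x.to_numpy())).fit()
        assert res["se"].iloc[0] > ols.bse[1]

    def test_constant_covariate_rejected(self):
        fam = pd.Series([0, 0, 1, 1], index=[f"s{i}" for i in range(4)])
        x = pd.Series(np.ones(4), index=fam.index)
        with pytest.raises(ValueError):
            pp.site_covariate_association(make_matrix(np.ones((1, 4))), x, fam)
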