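"""Background correction, normalization and Box-Cox behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import seronet as sn
from seronet import preprocess as pp
from tests.conftest import make_plate


def _plate_with_empty(values):
    n = len(values)
    mfi = pd.DataFrame(
        {"A1": values + [100.0], "A2": values + [100.0]},
        index=[f"E{i}" for i in range(n)] + ["S1"],
    )
    return make_plate(mfi, ["empty"] * n + ["sample"], ["antigen", "antigen"])


class TestBackground:
    def test_zero_variance_empty_wells(self):
        mfi = pd.DataFrame(
            {"A1": [10.0, 10.0, 10.0, 10.0, 50.0]},
            index=["E1", "E2", "E3", "E4", "S1"],
        )
        plate = make_plate(mfi, ["empty"] * 4 + ["sample"], ["antigen"])
        assert pp.estimate_background(plate) == 10.0

    def test_two_value_sample_sd(self):
        mfi = pd.DataFrame({"A1": [8.0, 12.0, 50.0]}, index=["E1", "E2", "S1"])
        plate = make_plate(mfi, ["empty", "empty", "sample"], ["antigen"])
        # mean 10 + sample SD sqrt(8); cross-checked by one-pass computation
        vals = np.array([8.0, 12.0])
        one_pass_sd = np.sqrt(
            (np.sum(vals**2) - len(vals) * vals.mean() ** 2) / (len(vals) - 1)
        )
        assert pp.estimate_background(plate) == pytest.approx(10 + one_pass_sd)
        assert pp.estimate_background(plate) == pytest.approx(12.8284271, abs=1e-6)

    def test_controls_excluded_and_errors(self, tiny_plate):
        bg = pp.estimate_background(tiny_plate)
        assert bg == pytest.approx(10.0)  # CTRL column ignored
        with pytest.raises(ValueError, match="empty"):
            # a plate without empty wells is rejected at construction
            make_plate(
                pd.DataFrame({"A1": [5.0]}, index=["S1"]), ["sample"], ["antigen"]
            )

    def test_per_analyte_option(self, tiny_plate):
        bg = pp.estimate_background(tiny_plate, per_analyte=True)
        assert list(bg.index) == ["A1", "A2", "A3"]
        assert (bg == 10.0).all()

    def test_monte_carlo_bound_on_synthetic_plates(self):
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            ds = sn.simulate_bead_array(sn.SimulationConfig(rng_seed=40_000 + seed))
            est = pp.estimate_background(ds.plate)
            hits += 120.0 <= est <= 140.0
        assert hits / n_seeds >= 0.95


class TestSubtractAndFloor:
    def test_arithmetic(self, tiny_plate):
        out = pp.subtract_and_floor(tiny_plate, 120.0)
        assert out.loc["S1", "A1"] == 381.0
        assert out.loc["S2", "A3"] == 1.0  # 100 <= background -> floored
        assert "CTRL" not in out.columns
        assert "E1" not in out.index

    def test_all_background_plate(self, tiny_plate):
        out = pp.subtract_and_floor(tiny_plate, 1e6)
        assert (out.to_numpy() == 1.0).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e5), min_size=2, max_size=10),
        st.floats(0, 1e4),
    )
    def test_floor_and_monotonicity(self, values, background):
        mfi = pd.DataFrame(
            {"A1": values + [0.0]}, index=[f"S{i}" for i in range(len(values))] + ["E1"]
        )
        plate = make_plate(mfi, ["sample"] * len(values) + ["empty"], ["antigen"])
        out = pp.subtract_and_floor(plate, background)["A1"].to_numpy()
        assert (out >= 1.0).all()
        order = np.argsort(values)
        assert (np.diff(out[order]) >= 0).all()


class TestJoinClinical:
    def test_study_shaped_join(self, dataset):
        bg = pp.estimate_background(dataset.plate)
        corrected = pp.subtract_and_floor(dataset.plate, bg)
        aligned, report = pp.join_clinical(corrected, dataset.clinical)
        assert aligned.shape[0] == 116
        assert report.n_dropped == 9
        assert list(aligned.index) == list(dataset.clinical.index)

    def test_identical_keys_and_single_patient(self):
        m = pd.DataFrame({"A1": [1.0, 2.0]}, index=["P1", "P2"])
        c = pd.DataFrame({"age": [70, 71]}, index=["P1", "P2"])
        aligned, report = pp.join_clinical(m, c)
        assert report.n_dropped == 0
        one, _ = pp.join_clinical(m, c.iloc[:1])
        assert one.shape == (1, 1)

    def test_join_idempotent(self):
        m = pd.DataFrame({"A1": [1.0, 2.0, 3.0]}, index=["P1", "P2", "P3"])
        c = pd.DataFrame({"age": [70, 71]}, index=["P2", "P1"])
        once, _ = pp.join_clinical(m, c)
        twice, report = pp.join_clinical(once, c)
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_dropped == 0

    def test_errors(self):
        m = pd.DataFrame({"A1": [1.0]}, index=["P1"])
        with pytest.raises(ValueError, match="overlap"):
            pp.join_clinical(m, pd.DataFrame({"age": [1]}, index=["X"]))
        dup = pd.DataFrame({"A1": [1.0, 2.0]}, index=["P1", "P1"])
        with pytest.raises(ValueError, match="duplicate"):
            pp.join_clinical(dup, pd.DataFrame({"age": [1]}, index=["P1"]))


class TestRSN:
    def _matrix(self, seed=0, n=20, m=30):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1.2, m)
        rows = np.exp2(base + rng.normal(0, 0.4, (n, m)))
        return pd.DataFrame(rows, index=[f"P{i}" for i in range(n)], columns=[f"A{j}" for j in range(m)])

    def test_identity_patient_unchanged(self):
        # build rows symmetric around a profile so the per-antigen median
        # (the virtual reference) equals patient 0 exactly
        rng = np.random.default_rng(0)
        profile = np.exp2(rng.normal(8, 1.2, 30))
        d1 = np.exp2(rng.uniform(0.1, 0.5, 30))
        d2 = np.exp2(rng.uniform(0.1, 0.5, 30))
        mat = pd.DataFrame(
            [profile, profile * d1, profile / d1, profile * d2, profile / d2]
        )
        out = pp.robust_spline_normalize(mat)
        np.testing.assert_allclose(out.iloc[0], profile, rtol=1e-6)

    def test_scaled_patient_recovers_reference(self):
        mat = self._matrix()
        ref = mat.median(axis=0)
        mat.iloc[0] = 2.0 * ref
        out = pp.robust_spline_normalize(mat)
        np.testing.assert_allclose(out.iloc[0], ref, rtol=0.02)

    def test_monotone_map_matches_isotonic_oracle(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(4, 12, 80))
        y = 0.7 * x + 0.02 * x**2 + rng.normal(0, 0.05, 80)  # smooth monotone
        f = pp._monotone_map(x, y, n_knots=6)
        iso = IsotonicRegression().fit(x, y)
        grid = np.linspace(x.min(), x.max(), 50)
        assert np.median(np.abs(f(grid) - iso.predict(grid))) < 0.15

    def test_quantile_mode_equalizes_sorted_values(self):
        mat = self._matrix(n=2)
        out = pp.robust_spline_normalize(mat, mode="quantile")
        a = np.sort(out.iloc[0].to_numpy())
        b = np.sort(out.iloc[1].to_numpy())
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_rank_order_preserved_within_patient(self):
        mat = self._matrix(seed=7)
        for mode, kw in [("rsn", {}), ("rsn", {"n_knots": 5}), ("quantile", {})]:
            out = pp.robust_spline_normalize(mat, mode=mode, **kw)
            for i in range(mat.shape[0]):
                x = mat.iloc[i].to_numpy()
                y = out.iloc[i].to_numpy()
                order = np.argsort(x)
                # nondecreasing in the input order; ties allowed (flat map
                # segments may collapse neighbouring values)
                assert (np.diff(y[order]) >= -1e-12).all()
        rho = stats.spearmanr(mat.iloc[0], pp.robust_spline_normalize(mat).iloc[0])[0]
        assert rho == pytest.approx(1.0)

    def test_between_patient_deviation_shrinks_on_scale_shifted_data(self):
        mat = self._matrix(seed=2, n=6)
        scales = [0.5, 0.8, 1.0, 1.3, 2.0, 3.0]
        shifted = mat.mul(scales, axis=0)
        out = pp.robust_spline_normalize(shifted)
        pre = np.log2(shifted.to_numpy())
        post = np.log2(out.to_numpy())
        mad_pre = np.abs(pre[0] - pre[5]).mean()
        mad_post = np.abs(post[0] - post[5]).mean()
        assert mad_post <= mad_pre

    def test_floor_values_preserved(self):
        mat = self._matrix(seed=5)
        mat.iloc[:, 0] = 1.0  # background-floored antigen
        out = pp.robust_spline_normalize(mat)
        assert (out.iloc[:, 0] == 1.0).all()

    def test_rank_selection_variant_runs(self):
        mat = self._matrix(seed=9)
        out = pp.robust_spline_normalize(mat, selection="rank", n_knots=4)
        assert out.shape == mat.shape

    def test_errors(self):
        small = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="at least 8"):
            pp.robust_spline_normalize(small)
        neg = pd.DataFrame(np.full((3, 9), -1.0))
        with pytest.raises(ValueError, match="positive"):
            pp.robust_spline_normalize(neg)


class TestBoxCox:
    def test_log_branch_closed_form(self):
        assert pp._boxcox_apply(np.array([8.0]), 0.0)[0] == pytest.approx(np.log(8))

    @pytest.mark.parametrize("lam_true,mu,sd", [(0.0, 0.0, 1.0), (0.5, 2.0, 1.0)])
    def test_lambda_recovery(self, lam_true, mu, sd):
        rng = np.random.default_rng(12)
        y = rng.normal(mu, sd, 500)
        x = np.exp(y) if lam_true == 0 else (1 + lam_true * y) ** (1 / lam_true)
        assert abs(pp.boxcox_lambda(x) - lam_true) < 0.2

    def test_matches_scipy_mle_oracle(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            x = np.exp(rng.normal(1, 0.7, 300))
            assert pp.boxcox_lambda(x) == pytest.approx(stats.boxcox(x)[1], abs=1e-3)

    def test_constant_column_flagged_identity(self):
        mat = pd.DataFrame({"A": [5.0, 5.0, 5.0], "B": [1.0, 2.0, 3.0]})
        res = pp.boxcox_transform(mat)
        assert res.flagged_constant == ("A",)
        assert res.lambdas["A"] == 1.0

    def test_offset_rule(self):
        mat = pd.DataFrame({"A": [-5.0, 0.0, 3.0]})
        res = pp.boxcox_transform(mat)
        assert res.offset == 6.0  # 1 - (-5)


class TestZeroVarianceFilter:
    def test_constant_column_removed(self):
        mat = pd.DataFrame({"A": [1.0, 1.0], "B": [1.0, 2.0]})
        out, removed = pp.zero_variance_filter(mat)
        assert removed == ["A"]
        assert list(out.columns) == ["B"]

    def test_full_variance_untouched(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        out, removed = pp.zero_variance_filter(mat)
        assert removed == []

    def test_all_removed_errors(self):
        mat = pd.DataFrame({"A": [1.0, 1.0]})
        with pytest.raises(ValueError, match="every antigen"):
            pp.zero_variance_filter(mat)

    def test_planted_low_tier_antigens(self, dataset, pipeline):
        tiers = pd.Series(dataset.truth.tier_of_patient)
        low = [p for p in pipeline.values.index if tiers[p] == "low"]
        _, removed = pp.zero_variance_filter(pipeline.values, scope=low)
        assert sorted(removed) == sorted(dataset.truth.zero_variance_antigens)


def test_pipeline_shape_and_provenance(pipeline):
    assert pipeline.values.shape == (116, 92)
    assert pipeline.exclusions.n_dropped == 9
    assert pipeline.corrected is not None
    assert np.isfinite(pipeline.lambdas).all()
    assert not pipeline.values.isna().any().any()
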