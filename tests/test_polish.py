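import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone


from tampor.polish import (
    TamporCorrector,
    batch_factor,
    column_center,
    denominator_median,
    frobenius_delta,
    naive_gis_ratio,
    restore_row_scale,
    resolve_mode,
    rowwise_ratio_step,
    run_tampor,
)

from conftest import mk_annotation, mk_matrix, random_dataset


def tukey_median_polish(mat, n_iter=500, tol=1e-12):
    """Independent row-then-column median-sweep oracle; returns the residual."""
    r = mat.copy()
    for _ in range(n_iter):
        rm = np.median(r, axis=1)
        r = r - rm[:, None]
        cm = np.median(r, axis=0)
        r = r - cm[None, :]
        if np.abs(rm).max() < tol and np.abs(cm).max() < tol:
            break
    return r


class TestModeResolution:
    @pytest.mark.parametrize(
        "alias,canonical",
        [("noGIS", "noGIS"), ("nogis", "noGIS"), ("GIS", "gis_only"),
         ("gis-only", "gis_only"), ("useAllNonGIS", "gis_plus_nonGIS"),
         ("gis_plus_nonGIS", "gis_plus_nonGIS")],
    )
    def test_aliases(self, alias, canonical):
        assert resolve_mode(alias) == canonical

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown mode"):
            resolve_mode("combat")


class TestDenominatorMedian:
    def test_odd_count(self):
        m = mk_matrix([[2.0, 4.0, 8.0]])
        ann = mk_annotation(m.columns, ["b1"] * 3)
        assert denominator_median(m, ann, "b1", "noGIS").iloc[0] == 4

    def test_even_count_mean_of_central_pair(self):
        m = mk_matrix([[2.0, 8.0]])
        ann = mk_annotation(m.columns, ["b1"] * 2)
        assert denominator_median(m, ann, "b1", "noGIS").iloc[0] == 5

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            vals = rng.lognormal(2, 1, (5, 7))
            m = mk_matrix(vals)
            ann = mk_annotation(m.columns, ["b1"] * 7)
            d = denominator_median(m, ann, "b1", "noGIS")
            for i in range(5):
                assert d.iloc[i] == sorted(vals[i])[3]  # sort-and-pick

    def test_gis_mode_requires_gis(self):
        m = mk_matrix([[1.0, 2.0]])
        ann = mk_annotation(m.columns, ["b1", "b1"])
        with pytest.raises(ValueError, match="b1.*no GIS"):
            denominator_median(m, ann, "b1", "gis_only")

    def test_all_missing_denominator_is_nan(self):
        m = mk_matrix([[np.nan, np.nan, 3.0], [1.0, 2.0, 3.0]],
                      samples=["g1", "g2", "c1"])
        ann = mk_annotation(m.columns, ["b1"] * 3, [True, True, False])
        d = denominator_median(m, ann, "b1", "gis_only")
        assert np.isnan(d.iloc[0]) and d.iloc[1] == 1.5


class TestBatchFactor:
    def test_gis_only_all_ones(self, rng):
        m, ann = random_dataset(rng)
        bf = batch_factor(m, ann, "gis_only")
        assert (bf.m.to_numpy() == 1).all()
        assert (bf.grand.to_numpy() == 1).all()

    def test_ratio_of_medians(self):
        m = mk_matrix([[6.0, 10.0, 4.0]], samples=["c1", "c2", "g1"])
        ann = mk_annotation(m.columns, ["b1"] * 3, [False, False, True])
        bf = batch_factor(m, ann, "gis_plus_nonGIS")
        assert bf.m.iloc[0, 0] == 2.0  # median{6,10}=8 over GIS 4

    def test_grand_median_and_multipliers(self):
        # batches with M = 0.5, 1, 2 -> grand 1, second-term multipliers 2, 1, 0.5
        samples = ["c1", "g1", "c2", "g2", "c3", "g3"]
        m = mk_matrix([[2.0, 4.0, 4.0, 4.0, 8.0, 4.0]], samples=samples)
        ann = mk_annotation(samples, ["b1", "b1", "b2", "b2", "b3", "b3"],
                            [False, True] * 3)
        bf = batch_factor(m, ann, "gis_plus_nonGIS")
        np.testing.assert_allclose(bf.m.iloc[0], [0.5, 1.0, 2.0])
        assert bf.grand.iloc[0] == 1.0
        np.testing.assert_allclose(bf.grand.iloc[0] / bf.m.iloc[0], [2.0, 1.0, 0.5])

    def test_requires_nongis_samples(self):
        m = mk_matrix([[1.0, 2.0]], samples=["g1", "g2"])
        ann = mk_annotation(m.columns, ["b1", "b1"], [True, True])
        with pytest.raises(ValueError, match="no non-GIS"):
            batch_factor(m, ann, "gis_plus_nonGIS")


class TestRatioStep:
    def test_single_batch_nogis(self):
        m = mk_matrix([[2.0, 4.0, 8.0]])
        ann = mk_annotation(m.columns, ["b1"] * 3)
        r = rowwise_ratio_step(m, ann, "noGIS")
        np.testing.assert_allclose(r.iloc[0], [0.5, 1.0, 2.0])

    def test_gis_plus_nongis_hand_example(self):
        # batch A: GIS median 4, non-GIS median 8; batch B: GIS 5, non-GIS 5
        # -> M = {2, 1}, grand = 1.5; a value of 8 in batch A maps to
        # 8/4 * 1.5/2 = 1.5
        samples = ["a1", "a2", "a3", "ag", "b1", "b2", "b3", "bg"]
        m = mk_matrix([[6.0, 8.0, 10.0, 4.0, 5.0, 5.0, 5.0, 5.0]], samples=samples)
        ann = mk_annotation(samples, ["A"] * 4 + ["B"] * 4,
                            [False, False, False, True, False, False, False, True])
        r = rowwise_ratio_step(m, ann, "useAllNonGIS")
        assert r.loc["F0", "a2"] == pytest.approx(1.5, rel=1e-12)

    def test_denominator_set_median_is_one(self, rng):
        # the ratio step recenters each batch's denominator-set median at
        # exactly grand/M (= 1 in noGIS and gis_only modes)
        m, ann = random_dataset(rng, n_features=11, n_batches=3, per_batch=4, n_gis=3)
        for mode, denom_gis in [("noGIS", False), ("gis_only", True)]:
            r = rowwise_ratio_step(m, ann, mode)
            for b in ann["batch"].unique():
                cols = ann.index[(ann["batch"] == b) & (ann["is_gis"] | (not denom_gis))]
                med = r[list(cols)].median(axis=1)
                np.testing.assert_allclose(med, 1.0, atol=1e-12)

    def test_fixed_point_batch_neutrality(self, rng):
        # after convergence the effective centering set (non-GIS medians in
        # gis_plus_nonGIS mode) is equalized across batches
        m, ann = random_dataset(rng, n_features=16, n_batches=3, per_batch=6, n_gis=2)
        res = run_tampor(m, ann, mode="gis_plus_nonGIS", tolerance=1e-12,
                         max_iterations=3000)
        assert res.converged
        meds = {}
        for b in ann["batch"].unique():
            cols = ann.index[(ann["batch"] == b) & ~ann["is_gis"]]
            meds[b] = res.corrected[list(cols)].median(axis=1)
        ref = meds.pop(list(meds)[0])
        for other in meds.values():
            # equal per row up to a single row-independent batch factor
            ratio = (other / ref).to_numpy()
            np.testing.assert_allclose(ratio / np.median(ratio), 1.0, atol=1e-6)

    def test_median_robust_to_minority_perturbation(self, rng):
        # perturbing m of n denominator values leaves the median between the
        # original order statistics (k-m) and (k+m)
        for _ in range(30):
            vals = np.sort(rng.lognormal(3, 1, 7))
            n_pert = int(rng.integers(1, 4))  # strict minority of 7
            idx = rng.choice(7, n_pert, replace=False)
            pert = vals.copy()
            pert[idx] = rng.lognormal(3, 5, n_pert)  # arbitrary magnitudes
            new_med = np.median(pert)
            assert vals[3 - n_pert] <= new_med <= vals[3 + n_pert]


class TestColumnCenter:
    def test_basic_and_identity(self):
        c = column_center(mk_matrix([[0.0], [1.0], [2.0]]))
        np.testing.assert_allclose(c.to_numpy().ravel(), [-1, 0, 1])
        again = column_center(c)
        pd.testing.assert_frame_equal(again, c)

    def test_post_condition_median_zero_with_missing(self, rng):
        vals = rng.normal(0, 3, (21, 6))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        c = column_center(mk_matrix(vals))
        for j in range(6):
            col = c.iloc[:, j].dropna().to_numpy()
            assert np.median(np.sort(col)) == pytest.approx(0, abs=1e-12)

    def test_all_missing_column_errors(self):
        m = mk_matrix([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="s1"):
            column_center(m)


class TestRestoreRowScale:
    def test_examples(self):
        out = restore_row_scale(mk_matrix([[0.0]]), pd.Series([100.0], index=["F0"]))
        assert out.iloc[0, 0] == 100
        out = restore_row_scale(mk_matrix([[-1.0, 0.0, 1.0]]),
                                pd.Series([8.0], index=["F0"]))
        np.testing.assert_allclose(out.iloc[0], [4, 8, 16])

    def test_round_trip_identity(self, rng):
        vals = rng.lognormal(3, 2, (9, 5))
        m = mk_matrix(vals)
        med = m.median(axis=1)
        back = restore_row_scale(np.log2(m.div(med, axis=0)), med)
        np.testing.assert_allclose(back.to_numpy(), vals, rtol=1e-12)


class TestFrobeniusDelta:
    def test_identical_zero(self, rng):
        a = rng.normal(size=(4, 5))
        assert frobenius_delta(a, a) == 0

    def test_hand_example(self):
        assert frobenius_delta([[3.0, 4.0]], [[6.0, 8.0]]) == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            a = rng.normal(size=(6, 4))
            b = rng.normal(size=(6, 4))
            a[rng.random(a.shape) < 0.2] = np.nan
            b[np.isnan(a)] = np.nan
            expect = abs(
                np.sqrt(sum(x * x for x in a.ravel() if not np.isnan(x)))
                - np.sqrt(sum(x * x for x in b.ravel() if not np.isnan(x)))
            )
            assert frobenius_delta(a, b) == pytest.approx(expect, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            frobenius_delta(np.ones((2, 2)), np.ones((2, 3)))


class TestRunTampor:
    def test_idempotent_on_converged_output(self, rng):
        # a converged output re-polished with its stored restoration
        # constants is an exact fixed point
        m, ann = random_dataset(rng, n_features=16, n_batches=2, per_batch=6, n_gis=2)
        first = run_tampor(m, ann, mode="gis_plus_nonGIS", tolerance=1e-12,
                           max_iterations=3000)
        assert first.converged
        second = run_tampor(first.corrected, ann, mode="gis_plus_nonGIS",
                            tolerance=1e-8, row_medians=first.row_medians)
        assert second.trace.iterations_run == 1
        assert second.trace.delta[-1] < 1e-8
        np.testing.assert_allclose(second.corrected.to_numpy(),
                                   first.corrected.to_numpy(), rtol=1e-9)

    def test_constant_row_matrix_is_exact_fixed_point(self, rng):
        # a matrix whose rows are constant polishes to itself in one step
        levels = rng.lognormal(5, 2, 12)
        vals = np.tile(levels[:, None], (1, 9))
        m = mk_matrix(vals)
        ann = mk_annotation(m.columns, ["b1"] * 5 + ["b2"] * 4)
        res = run_tampor(m, ann, mode="noGIS")
        assert res.trace.iterations_run == 1
        np.testing.assert_allclose(res.corrected.to_numpy(), vals, rtol=1e-12)

    def test_mode_alias_reaches_same_result(self, rng):
        m, ann = random_dataset(rng, n_batches=2, n_gis=2)
        a = run_tampor(m, ann, mode="useAllNonGIS")
        b = run_tampor(m, ann, mode="gis_plus_nonGIS")
        assert a.config["mode"] == "gis_plus_nonGIS"
        pd.testing.assert_frame_equal(a.corrected, b.corrected)

    def test_single_batch_nogis_matches_median_polish_oracle(self, rng):
        # odd sample count so abundance- and log-space medians coincide
        vals = 2.0 ** rng.normal(10, 2, (20, 9))
        m = mk_matrix(vals)
        ann = mk_annotation(m.columns, ["b1"] * 9)
        res = run_tampor(m, ann, mode="noGIS", tolerance=1e-12, max_iterations=3000)
        resid_oracle = tukey_median_polish(np.log2(vals))
        out_log = np.log2(res.corrected.to_numpy())
        resid_ours = out_log - np.median(out_log, axis=1)[:, None]
        np.testing.assert_allclose(resid_ours, resid_oracle, atol=1e-6)

    def test_trace_invariants(self, rng):
        m, ann = random_dataset(rng)
        res = run_tampor(m, ann, mode="noGIS")
        tr = res.trace
        assert len(tr.delta) == tr.iterations_run == res.trace.to_frame().shape[0]
        assert np.isfinite(tr.delta).all()
        assert tr.converged and tr.delta[-1] < 1e-8

    def test_nonconvergence_is_warning(self, rng):
        m, ann = random_dataset(rng)
        with pytest.warns(RuntimeWarning, match="preliminary"):
            res = run_tampor(m, ann, mode="noGIS", max_iterations=2)
        assert not res.converged

    def test_missing_pattern_preserved(self, rng):
        m, ann = random_dataset(rng, missing_frac=0.15)
        res = run_tampor(m, ann, mode="gis_only")
        # output missing >= input missing; no value invented
        inp = m.isna().to_numpy()
        out = res.corrected.isna().to_numpy()
        assert (out | ~inp).all() or (out[inp]).all()
        assert out[inp].all()

    def test_rejects_nonpositive(self):
        m = mk_matrix([[1.0, 0.0], [2.0, 3.0]])
        ann = mk_annotation(m.columns, ["b1", "b1"])
        with pytest.raises(ValueError, match="sanitize"):
            run_tampor(m, ann, mode="noGIS")

    def test_config_validation(self, rng):
        m, ann = random_dataset(rng)
        with pytest.raises(ValueError):
            run_tampor(m, ann, mode="noGIS", tolerance=0)
        with pytest.raises(ValueError):
            run_tampor(m, ann, mode="noGIS", max_iterations=0)
        with pytest.raises(ValueError):
            run_tampor(m, ann, mode="noGIS", convergence="bogus")

    def test_delta_norm_variant_converges(self, rng):
        m, ann = random_dataset(rng, n_features=12, n_batches=2, per_batch=4)
        res = run_tampor(m, ann, mode="noGIS", convergence="delta_norm",
                         tolerance=1e-10, max_iterations=3000)
        assert res.converged


class TestNaiveGisRatio:
    def test_mean_center_example(self):
        m = mk_matrix([[10.0, 4.0, 6.0]], samples=["c1", "g1", "g2"])
        ann = mk_annotation(m.columns, ["b1"] * 3, [False, True, True])
        r = naive_gis_ratio(m, ann, center="mean")
        assert r.loc["F0", "c1"] == pytest.approx(2.0)

    def test_gis_self_ratio_is_one(self):
        m = mk_matrix([[10.0, 4.0]], samples=["c1", "g1"])
        ann = mk_annotation(m.columns, ["b1"] * 2, [False, True])
        r = naive_gis_ratio(m, ann, center="median")
        assert r.loc["F0", "g1"] == 1.0

    def test_equals_gis_only_step_with_single_gis(self, rng):
        m, ann = random_dataset(rng, n_batches=3, per_batch=4, n_gis=1)
        step = rowwise_ratio_step(m, ann, "gis_only")
        naive = naive_gis_ratio(m, ann, center="median")
        pd.testing.assert_frame_equal(step, naive)

    def test_batch_without_gis_errors(self):
        m = mk_matrix([[1.0, 2.0]], samples=["c1", "c2"])
        ann = mk_annotation(m.columns, ["b1", "b1"])
        with pytest.raises(ValueError, match="no GIS"):
            naive_gis_ratio(m, ann)


class TestTamporCorrector:
    def test_sklearn_protocol(self, rng):
        est = TamporCorrector(mode="noGIS", tolerance=1e-6)
        params = est.get_params()
        assert params["mode"] == "noGIS" and params["tolerance"] == 1e-6
        est2 = clone(est).set_params(max_iterations=50)
        assert est2.get_params()["max_iterations"] == 50

    def test_fit_attributes_and_equivalence(self, rng):
        m, ann = random_dataset(rng, n_batches=2, n_gis=2)
        est = TamporCorrector(mode="gis_only").fit(m, annotation=ann)
        ref = run_tampor(m, ann, mode="gis_only")
        pd.testing.assert_frame_equal(est.corrected_, ref.corrected)
        assert est.converged_ and est.n_iter_ == ref.trace.iterations_run
        pd.testing.assert_series_equal(est.row_medians_, ref.row_medians)

    def test_fit_with_arrays(self, rng):
        m, ann = random_dataset(rng, n_batches=2)
        out = TamporCorrector(mode="noGIS").fit_transform(
            m, batch=ann["batch"].to_numpy())
        assert out.shape == m.shape

    def test_transform_checks_columns(self, rng):
        m, ann = random_dataset(rng, n_batches=2)
        est = TamporCorrector(mode="noGIS").fit(m, annotation=ann)
        with pytest.raises(ValueError, match="columns"):
            est.transform(m.iloc[:, :3])

    def test_unfitted_transform_raises(self, rng):
        m, _ = random_dataset(rng)
        with pytest.raises(ValueError, match="not fitted"):
            TamporCorrector().transform(m)
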