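"""RT anchoring/correction, alignment, gap filling and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionflow.align_normalize import (
    align_features,
    evaluate_rt_model,
    fill_gaps,
    fit_rt_model,
    pqn_normalize,
    qc_drift_correct,
    select_rt_anchors,
    sum_normalize,
)
from ionflow.raw_io import write_synthetic_mzml, read_run

from conftest import make_run


def ref_features(n=60, seed=5):
    rng = np.random.default_rng(seed)
    mz = np.sort(rng.uniform(100, 900, n))
    return pd.DataFrame(
        {
            "mz": mz,
            "rt": rng.uniform(0.5, 10, n),
            "height": rng.uniform(1e4, 1e6, n),
            "noise_score": rng.uniform(0, 0.25, n),
        }
    )


class TestSelectRtAnchors:
    def test_neighbor_gap_condition(self):
        feats = pd.DataFrame(
            {
                "mz": [100.000, 100.005, 200.000],
                "rt": [1.0, 1.1, 2.0],
                "height": [10.0, 9.0, 8.0],
                "noise_score": [0.0, 0.0, 0.0],
            }
        )
        a = select_rt_anchors(feats, mz_tol=0.01)
        kept = pd.concat([a.train, a.test])["mz"].tolist()
        assert kept == [200.000]

    def test_noisy_feature_rejected(self):
        feats = ref_features()
        feats.loc[10, "noise_score"] = 0.35
        a = select_rt_anchors(feats, noise_tol=0.3)
        assert feats.loc[10, "mz"] not in pd.concat([a.train, a.test])["mz"].values

    def test_top_k_tallest_retained(self):
        feats = ref_features(n=80)
        a = select_rt_anchors(feats, top_k=50)
        assert a.n == 50
        kept_heights = pd.concat([a.train, a.test])["height"]
        # the 50 kept anchors are the tallest eligible ones
        eligible = select_rt_anchors(feats, top_k=10**6)
        all_heights = pd.concat([eligible.train, eligible.test])["height"]
        assert set(kept_heights) == set(all_heights.nlargest(50))

    def test_train_test_alternate_by_rank(self):
        feats = ref_features()
        a = select_rt_anchors(feats)
        assert abs(len(a.train) - len(a.test)) <= 1
        # ranks interleave: tallest trains, next tests, ...
        assert a.train["height"].iloc[0] >= a.test["height"].iloc[0]


class TestRtModel:
    def test_identity_when_sample_equals_reference(self):
        feats = ref_features()
        anchors = select_rt_anchors(feats)
        model = fit_rt_model(anchors, feats)
        rts = feats["rt"].to_numpy()
        assert np.allclose(model(rts), rts, atol=1e-9)

    def test_linear_interpolation_between_anchors(self):
        anchors = pd.DataFrame(
            {
                "mz": [100.0, 200.0, 300.0, 400.0],
                "rt": [1.0, 2.0, 3.0, 4.0],
                "height": [4.0, 3.0, 2.0, 1.0],
            }
        )
        sample = anchors.copy()
        sample["rt"] = [1.1, 2.2, 3.3, 4.4]
        model = fit_rt_model(anchors, sample)
        # a sample rt halfway between matched anchors maps halfway back
        assert model(1.65) == pytest.approx(1.5)

    def test_displaced_anchor_removed_as_outlier(self):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 900, 30))
        ref = pd.DataFrame(
            {"mz": mz, "rt": np.linspace(1, 10, 30), "height": np.arange(30, 0, -1.0)}
        )
        sample = ref.copy()
        sample["rt"] = ref["rt"] * 1.02 + 0.05
        sample.loc[13, "rt"] = 0.2  # wildly off the trend
        model = fit_rt_model(ref, sample)
        clean = fit_rt_model(ref.drop(13), sample.drop(13))
        q = np.linspace(1.5, 9.5, 17)
        assert np.allclose(model(q * 1.02 + 0.05), clean(q * 1.02 + 0.05), atol=1e-6)

    def test_monotonicity_property(self):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(100, 900, 40))
        ref = pd.DataFrame(
            {"mz": mz, "rt": np.linspace(0.5, 11, 40), "height": rng.uniform(1, 10, 40)}
        )
        sample = ref.copy()
        sample["rt"] = ref["rt"] + 0.3 * np.sin(ref["rt"])  # nonlinear drift
        model = fit_rt_model(ref, sample)
        q = np.linspace(0, 12, 300)
        out = model(q)
        assert np.all(np.diff(out) >= -1e-12)

    def test_too_few_anchors_identity_with_warning(self):
        anchors = pd.DataFrame({"mz": [100.0], "rt": [1.0], "height": [1.0]})
        sample = pd.DataFrame({"mz": [500.0], "rt": [9.0], "height": [1.0]})
        with pytest.warns(UserWarning):
            model = fit_rt_model(anchors, sample)
        assert model.identity
        assert model(3.3) == 3.3

    def test_json_round_trip(self, tmp_path):
        from ionflow.align_normalize import RtModel

        m = RtModel(sample_rt=np.array([1.0, 2.0]), reference_rt=np.array([1.1, 2.2]))
        m.to_json(tmp_path / "m.json")
        m2 = RtModel.from_json(tmp_path / "m.json")
        assert np.array_equal(m.sample_rt, m2.sample_rt)
        assert m2(1.5) == m(1.5)


class TestEvaluateRtModel:
    def test_no_drift_zero_shift(self):
        feats = ref_features()
        anchors = select_rt_anchors(feats)
        model = fit_rt_model(anchors, feats)
        pairs = pd.DataFrame({"ref_rt": anchors.test["rt"], "samp_rt": anchors.test["rt"]})
        ev = evaluate_rt_model(model, pairs)
        assert ev.shift_before_s == 0.0
        assert ev.shift_after_s == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_drift_recovery(self):
        """Smooth drift rt' = 1.02 rt + 0.05: test-anchor shift shrinks > 80%."""
        feats = ref_features(n=80)
        anchors = select_rt_anchors(feats)
        sample = feats.copy()
        sample["rt"] = feats["rt"] * 1.02 + 0.05
        model = fit_rt_model(anchors, sample)
        test = anchors.test
        pairs = pd.DataFrame(
            {"ref_rt": test["rt"], "samp_rt": test["rt"] * 1.02 + 0.05}
        )
        ev = evaluate_rt_model(model, pairs)
        assert ev.shift_before_s > 1.0
        assert ev.shift_after_s < 0.2 * ev.shift_before_s

    def test_missing_test_anchor_excluded(self):
        from ionflow.align_normalize import RtModel

        model = RtModel(identity=True)
        pairs = pd.DataFrame(
            {"ref_rt": [1.0, 2.0], "samp_rt": [1.1, np.nan]}
        )
        ev = evaluate_rt_model(model, pairs)
        assert ev.shift_before_s == pytest.approx(6.0)  # only the matched pair


def peak_df(rows):
    return pd.DataFrame(rows, columns=["mz", "rt", "height"])


class TestAlignFeatures:
    def test_shared_peak_single_row(self):
        tables = {
            f"s{i}": peak_df([(300.0004 + i * 1e-4, 5.0 + 0.01 * i, 1e5)])
            for i in range(3)
        }
        table = align_features(tables)
        assert len(table.features) == 1
        assert table.features.loc[0, "detection_rate"] == 1.0

    def test_rt_separation_beyond_tolerance_two_rows(self):
        tables = {
            "a": peak_df([(300.0, 5.0, 1e5)]),
            "b": peak_df([(300.0, 5.3, 1e5)]),
        }
        assert len(align_features(tables, rt_tol=0.2).features) == 2

    def test_mz_separation_beyond_tolerance_two_rows(self):
        tables = {
            "a": peak_df([(300.00, 5.0, 1e5)]),
            "b": peak_df([(300.02, 5.0, 1e5)]),
        }
        assert len(align_features(tables, mz_tol=0.01).features) == 2

    def test_idempotent_on_single_sample(self):
        rng = np.random.default_rng(4)
        df = peak_df(
            [
                (m, r, h)
                for m, r, h in zip(
                    np.sort(rng.uniform(100, 900, 25)),
                    rng.uniform(1, 10, 25),
                    rng.uniform(1e4, 1e6, 25),
                )
            ]
        )
        t1 = align_features({"a": df})
        again = t1.features.rename(columns={})[["mz", "rt"]].copy()
        again["height"] = t1.intensities["a"]
        t2 = align_features({"a": again})
        assert len(t2.features) == len(t1.features)
        assert np.allclose(
            np.sort(t2.features["mz"]), np.sort(t1.features["mz"])
        )


class TestFillGaps:
    def _run_with_signal(self, height=5e4):
        tuples = []
        for si in range(20):
            y = height * np.exp(-((si - 10) ** 2) / 8.0)
            tuples.append((si * 0.01, [400.0], [y]))
        return make_run(tuples)

    def test_missing_cell_filled_with_window_max(self):
        tables = {
            "a": peak_df([(400.0, 0.10, 5e4)]),
            "b": peak_df([(700.0, 0.10, 1e5)]),
        }
        table = align_features(tables)
        runs = {"b": self._run_with_signal()}
        table = fill_gaps(table, runs, rt_window=0.05)
        row = table.features.index[np.isclose(table.features["mz"], 400.0)][0]
        assert table.status.loc[row, "b"] == "gap_filled"
        assert table.intensities.loc[row, "b"] == pytest.approx(5e4)

    def test_blank_window_zero_flagged(self):
        tables = {
            "a": peak_df([(400.0, 0.10, 5e4)]),
            "b": peak_df([(700.0, 0.10, 1e5)]),
        }
        table = align_features(tables)
        blank = make_run([(si * 0.01, [], []) for si in range(20)])
        table = fill_gaps(table, {"b": blank})
        row = table.features.index[np.isclose(table.features["mz"], 400.0)][0]
        assert table.intensities.loc[row, "b"] == 0.0
        assert table.status.loc[row, "b"] == "gap_filled"

    def test_detected_cells_untouched_and_missing_run_warns(self):
        tables = {
            "a": peak_df([(400.0, 0.10, 5e4)]),
            "b": peak_df([(700.0, 0.10, 1e5)]),
        }
        table = align_features(tables)
        before = table.intensities.copy()
        with pytest.warns(UserWarning):
            table = fill_gaps(table, {})
        detected = (table.status == "detected").to_numpy()
        assert np.array_equal(
            table.intensities.to_numpy()[detected], before.to_numpy()[detected]
        )


class TestPqn:
    def _table(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(1e4, 1e6, 30)
        return pd.DataFrame({"a": base, "b": base, "c": base})

    def test_identical_samples_unchanged(self):
        tbl = self._table()
        norm, f = pqn_normalize(tbl)
        assert np.allclose(f, 1.0)
        assert np.allclose(norm, tbl)

    def test_doubled_sample_rescaled(self):
        tbl = self._table()
        tbl["b"] = tbl["a"] * 2
        norm, f = pqn_normalize(tbl)
        assert f["b"] == pytest.approx(2.0)
        assert np.allclose(norm["b"], norm["a"])

    def test_mixed_dilution_factor_is_shared_median(self):
        tbl = self._table()
        x = tbl["a"].to_numpy().copy()
        x[:20] *= 2  # two thirds doubled -> median quotient 2
        tbl["b"] = x
        _, f = pqn_normalize(tbl)
        assert f["b"] == pytest.approx(2.0)

    @given(c=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c):
        tbl = self._table()
        _, f1 = pqn_normalize(tbl)
        tbl2 = tbl.copy()
        tbl2["b"] = tbl2["b"] * c
        _, f2 = pqn_normalize(
            tbl2, reference=tbl[["a", "c"]].median(axis=1).to_numpy()
        )
        assert f2["b"] == pytest.approx(c * f1["b"], rel=1e-9)

    def test_no_shared_features_rejected(self):
        tbl = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            pqn_normalize(tbl, reference=np.array([1.0, 0.0]))

    def test_sum_normalization_alternative(self):
        tbl = self._table()
        tbl["b"] = tbl["a"] * 3
        norm, _ = sum_normalize(tbl)
        assert np.allclose(norm["a"], norm["b"])


class TestQcDrift:
    def _drifting_table(self, n_samples=20, n_qc=6, slope=0.2):
        rng = np.random.default_rng(8)
        cols = [f"s{i}" for i in range(n_samples)]
        qc = [f"s{i}" for i in range(0, n_samples, n_samples // n_qc)][:n_qc]
        order = pd.Series({c: i + 1 for i, c in enumerate(cols)})
        base = rng.uniform(1e4, 1e6, 25)
        drift = 1 + slope * (order.to_numpy() - 1) / (n_samples - 1)
        data = np.outer(base, drift)
        return pd.DataFrame(data, columns=cols), order, qc

    def test_flat_qc_trend_table_unchanged(self):
        tbl, order, qc = self._drifting_table(slope=0.0)
        out, skipped = qc_drift_correct(tbl, order, qc)
        assert skipped == []
        assert np.allclose(out, tbl, rtol=1e-6)

    def test_linear_drift_reduces_qc_rsd(self):
        tbl, order, qc = self._drifting_table(slope=0.2)
        out, _ = qc_drift_correct(tbl, order, qc)

        def rsd(df):
            q = df[qc]
            return (q.std(axis=1) / q.mean(axis=1)).median()

        assert rsd(out) < rsd(tbl)

    def test_never_negative(self):
        tbl, order, qc = self._drifting_table()
        out, _ = qc_drift_correct(tbl, order, qc)
        assert (out >= 0).all().all()

    def test_feature_missing_in_most_qcs_skipped(self):
        tbl, order, qc = self._drifting_table()
        tbl.loc[0, qc[:4]] = 0.0
        out, skipped = qc_drift_correct(tbl, order, qc)
        assert 0 in skipped
        assert np.allclose(out.iloc[0], tbl.iloc[0])

    def test_too_few_qcs_rejected(self):
        tbl, order, qc = self._drifting_table()
        with pytest.raises(ValueError):
            qc_drift_correct(tbl, order, qc[:3])
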