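"""Pooling, percent error, summaries, equicorrelation forms, rho estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphopool import (
    NoiseModel,
    cs1mm_first_k,
    equicorr_pooled_sd,
    estimate_rho,
    expected_sqrt_curve,
    multires4,
    percent_error,
    pool,
    relative_reduction,
    scheme_adni,
    scheme_by_name,
    scheme_duration,
    scheme_errors,
    sigma_from_mean_error,
    simulate_study,
    summarize_errors,
)
from morphopool.morpho_io import TABLE_COLUMNS
from morphopool.precision import (
    AlignmentError,
    EmptySelectionError,
    EstimationError,
    PoolingScheme,
    break_pair,
    no_break_pair,
)

from conftest import cs1mm_design


def _mini_table(values_by_scan: dict[int, float], subject="s1", session=1,
                structure="Hippocampus") -> pd.DataFrame:
    rows = []
    for idx, v in values_by_scan.items():
        rows.append({
            "subject_id": subject, "group": "YA-CU", "session": session,
            "scan_type": "CS", "resolution_mm": 1.0,
            "block": "pre" if idx <= 4 else "post", "type_index": idx,
            "order_index": idx, "duration_s": 72, "structure": structure,
            "hemisphere": "left", "measure_class": "volume", "units": "mm3",
            "value": v,
        })
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


class TestPercentError:
    def test_identity(self):
        assert percent_error(100.0, 100.0) == 0.0

    def test_forced_by_formula(self):
        assert percent_error(102.0, 98.0) == pytest.approx(4.0)

    def test_hand_arithmetic(self):
        # 100 * 105.6 / 4155.5
        assert percent_error(4208.3, 4102.7) == pytest.approx(2.54121, abs=1e-5)

    @given(
        v1=st.floats(0.1, 1e6),
        v2=st.floats(0.1, 1e6),
        c=st.floats(0.01, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_nonnegative_scale_invariant(self, v1, v2, c):
        e = percent_error(v1, v2)
        assert e >= 0
        assert e == percent_error(v2, v1)
        assert percent_error(c * v1, c * v2) == pytest.approx(e, rel=1e-9, abs=1e-9)
        if v1 == v2:
            assert e == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_error(-2.0, 1.0)


class TestPool:
    def test_k1_is_identity(self, uncorrelated_table):
        pooled = pool(uncorrelated_table, cs1mm_first_k(1))
        raw = uncorrelated_table[uncorrelated_table["type_index"] == 1]
        merged = pooled.merge(
            raw, on=["subject_id", "session", "structure", "hemisphere", "measure_class"],
            suffixes=("_pooled", "_raw"),
        )
        np.testing.assert_allclose(merged["value_pooled"], merged["value_raw"])

    def test_arithmetic_mean(self):
        table = _mini_table({1: 10.0, 2: 12.0, 3: 14.0, 4: 16.0})
        pooled = pool(table, cs1mm_first_k(4))
        assert pooled["value"].iloc[0] == pytest.approx(13.0)

    def test_noiseless_pooling_exact(self, noiseless_table):
        p1 = pool(noiseless_table, cs1mm_first_k(1))
        p8 = pool(noiseless_table, cs1mm_first_k(8))
        merged = p1.merge(
            p8, on=["subject_id", "session", "structure", "hemisphere", "measure_class"]
        )
        np.testing.assert_allclose(merged["value_x"], merged["value_y"])

    def test_empty_selection_rejected(self):
        table = _mini_table({1: 10.0})
        scheme = PoolingScheme("none", k=1, scan_type="ADNI")
        with pytest.raises(EmptySelectionError):
            pool(table, scheme)

    def test_subject_with_missing_scans_dropped(self, caplog):
        full = pd.concat(
            [
                _mini_table({1: 10.0, 2: 12.0}, subject="s1", session=1),
                _mini_table({1: 11.0, 2: 13.0}, subject="s1", session=2),
                _mini_table({1: 10.0}, subject="s2", session=1),
                _mini_table({1: 10.5, 2: 11.0}, subject="s2", session=2),
            ],
            ignore_index=True,
        )
        with caplog.at_level("WARNING"):
            pooled = pool(full, cs1mm_first_k(2))
        assert set(pooled["subject_id"]) == {"s1"}
        assert "s2" in caplog.text


class TestSchemeErrors:
    def test_hand_built_two_subjects(self):
        table = pd.concat(
            [
                _mini_table({1: 100.0}, subject="a", session=1),
                _mini_table({1: 104.0}, subject="a", session=2),
                _mini_table({1: 4208.3}, subject="b", session=1),
                _mini_table({1: 4102.7}, subject="b", session=2),
            ],
            ignore_index=True,
        )
        err = scheme_errors(table, cs1mm_first_k(1))
        by_subject = err.set_index("subject_id")["percent_error"]
        assert by_subject["a"] == pytest.approx(percent_error(100.0, 104.0))
        assert by_subject["b"] == pytest.approx(percent_error(4208.3, 4102.7))

    def test_duplicated_session_gives_zero(self, uncorrelated_table):
        s1 = uncorrelated_table[uncorrelated_table["session"] == 1]
        mirrored = pd.concat([s1, s1.assign(session=2)], ignore_index=True)
        err = scheme_errors(mirrored, cs1mm_first_k(4))
        assert (err["percent_error"] == 0).all()

    def test_noiseless_all_zero(self, noiseless_table):
        err = scheme_errors(noiseless_table, cs1mm_first_k(8))
        assert (err["percent_error"] == 0).all()

    def test_subject_missing_session_excluded(self, uncorrelated_table, caplog):
        drop_subject = uncorrelated_table["subject_id"].iloc[0]
        table = uncorrelated_table[
            ~((uncorrelated_table["subject_id"] == drop_subject)
              & (uncorrelated_table["session"] == 2))
        ]
        with caplog.at_level("WARNING"):
            err = scheme_errors(table, cs1mm_first_k(1))
        assert drop_subject not in set(err["subject_id"])
        assert err["subject_id"].nunique() == 39


class TestSummaries:
    def _records(self, errors):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(errors))],
                "group": "YA-CU",
                "structure": "Hippocampus",
                "hemisphere": "left",
                "measure_class": "volume",
                "scheme": "test",
                "percent_error": errors,
            }
        )

    def test_sample_sd(self):
        summ = summarize_errors(self._records([1.0, 2.0, 3.0]), "per-measure")
        assert summ["mean_pct"].iloc[0] == pytest.approx(2.0)
        assert summ["sd_pct"].iloc[0] == pytest.approx(1.0)
        assert summ["sem_pct"].iloc[0] == pytest.approx(1.0 / math.sqrt(3))

    def test_singleton_sd_zero(self):
        summ = summarize_errors(self._records([1.5]), "per-measure")
        assert summ["sd_pct"].iloc[0] == 0.0

    def test_group_bookkeeping(self, small_table):
        err = scheme_errors(small_table, cs1mm_first_k(2))
        summ = summarize_errors(err, "per-group")
        assert set(summ["group"]) == {"YA-CU", "OA-CU", "MCI/AD"}

    def test_overall_aggregates_measures_first(self, uncorrelated_table):
        err = scheme_errors(uncorrelated_table, cs1mm_first_k(1))
        overall = summarize_errors(err, "overall", mode="measures")
        per_measure = summarize_errors(err, "per-measure")
        assert overall["n"].iloc[0] == 152
        assert overall["mean_pct"].iloc[0] == pytest.approx(per_measure["mean_pct"].mean())

    def test_record_mode_differs_in_n(self, uncorrelated_table):
        err = scheme_errors(uncorrelated_table, cs1mm_first_k(1))
        rec = summarize_errors(err, "overall", mode="records")
        assert rec["n"].iloc[0] == len(err)


class TestBenchmarks:
    def test_expected_sqrt_curve(self):
        assert expected_sqrt_curve(3.5, 1) == 3.5
        assert expected_sqrt_curve(3.01, 4) == pytest.approx(1.505)
        with pytest.raises(ValueError):
            expected_sqrt_curve(3.0, 0)

    def test_equicorr_limits(self):
        assert equicorr_pooled_sd(1.3, 0.0, 4) == pytest.approx(1.3 / 2)
        assert equicorr_pooled_sd(1.3, 1.0, 8) == pytest.approx(1.3)
        assert equicorr_pooled_sd(1.0, 0.2, 4) == pytest.approx(math.sqrt(1.6 / 4))
        with pytest.raises(ValueError):
            equicorr_pooled_sd(1.0, 1.5, 4)

    def test_relative_reduction_identity_and_forced(self):
        a = pd.DataFrame(
            {
                "subject_id": ["s1", "s2"], "group": "YA-CU",
                "structure": "Hippocampus", "hemisphere": "left",
                "measure_class": "volume", "scheme": "A",
                "percent_error": [2.0, 2.0],
            }
        )
        b = a.assign(scheme="B", percent_error=[1.0, 1.0])
        per_measure, summary = relative_reduction(a, b)
        assert summary["mean_percent_reduction"] == pytest.approx(50.0)
        _, same = relative_reduction(a, a)
        assert same["mean_delta_pct_points"] == 0.0
        with pytest.raises(AlignmentError):
            relative_reduction(a, b.assign(structure="Amygdala"))

    def test_pooling_reduction_follows_sqrt_law(self, uncorrelated_table):
        """With independent errors, k=4 pooling halves the error (~50%)."""
        err1 = scheme_errors(uncorrelated_table, cs1mm_first_k(1))
        err4 = scheme_errors(uncorrelated_table, cs1mm_first_k(4))
        _, summary = relative_reduction(err1, err4)
        assert summary["mean_percent_reduction"] == pytest.approx(50.0, abs=3.0)

    def test_mean_error_nonincreasing_in_k(self, uncorrelated_table):
        means = [
            summarize_errors(scheme_errors(uncorrelated_table, cs1mm_first_k(k)))[
                "mean_pct"
            ].iloc[0]
            for k in (1, 2, 4, 8)
        ]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_half_normal_link(self, uncorrelated_table):
        """Mean percent error ~ sqrt(2/pi) * SD of relative session diffs."""
        err = scheme_errors(uncorrelated_table, cs1mm_first_k(1))
        from morphopool.precision import _pooled_session_diffs

        _, diffs = _pooled_session_diffs(uncorrelated_table, 1, None)
        sd = np.std(diffs[:, 0], ddof=1)
        predicted = 100.0 * math.sqrt(2.0 / math.pi) * sd
        observed = err["percent_error"].mean()
        assert observed == pytest.approx(predicted, rel=0.03)


class TestEstimateRho:
    def test_fully_shared_error_clips_to_one(self):
        model = NoiseModel(sigma_session=0.02)
        table = simulate_study(model, cs1mm_design(30), seed=13)
        est = estimate_rho(table, n_boot=20, seed=1)
        assert est.rho == 1.0

    def test_degenerate_noiseless_fit_fails(self, noiseless_table):
        with pytest.raises(EstimationError):
            estimate_rho(noiseless_table, n_boot=5, seed=1)

    def test_recovers_moderate_rho(self):
        rho = 0.3
        sig = sigma_from_mean_error(3.0)
        model = NoiseModel(
            sigma_session=sig * math.sqrt(rho), sigma_scan=sig * math.sqrt(1 - rho)
        )
        table = simulate_study(model, cs1mm_design(120), seed=19)
        est = estimate_rho(table, n_boot=50, seed=2)
        assert est.rho == pytest.approx(rho, abs=0.06)
        assert est.ci_low <= est.rho <= est.ci_high

    def test_max_k_validation(self, uncorrelated_table):
        with pytest.raises(ValueError):
            estimate_rho(uncorrelated_table, max_k=1)


class TestSchemeDuration:
    @pytest.mark.parametrize(
        "scheme,seconds",
        [
            (cs1mm_first_k(4), 288),  # 4'48"
            (cs1mm_first_k(8), 576),  # 9'36"
            (multires4(), 305),  # 5'05"
            (scheme_adni(), 312),  # 5'12"
            (no_break_pair(), 144),
            (break_pair(), 144),
        ],
    )
    def test_durations(self, scheme, seconds):
        assert scheme_duration(scheme) == seconds

    def test_unknown_resolution_rejected(self):
        scheme = PoolingScheme("odd", k=1, scan_type="CS",
                               resolutions=frozenset({0.5}), type_indices=(1,))
        with pytest.raises(KeyError):
            scheme_duration(scheme)

    def test_scheme_by_name(self):
        assert scheme_by_name("cs1mm_first_4").k == 4
        assert scheme_by_name("ADNI").scan_type == "ADNI"
        with pytest.raises(KeyError):
            scheme_by_name("nope")
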