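"""Threshold calibration and screening-funnel gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rabmab.funnel import (
    FunnelConfig,
    FunnelReport,
    apply_funnel,
    calibrate_threshold,
    fit_johnson_su,
    percent,
    percent_inhibition,
    remove_outliers,
    threshold_correlation,
)
from rabmab.synthetic import (
    PanelSimConfig,
    generate_panel,
    johnson_su_quantile,
    johnson_su_sample,
)


class TestRemoveOutliers:
    def test_clean_normal_sample_barely_trimmed(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(1000)
        retained, removed = remove_outliers(values)
        assert len(removed) <= 10  # <= 1%

    def test_planted_extremes_exactly_removed(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal(1000)
        idx = np.array([10, 200, 400, 600, 990])
        values[idx] = 50.0
        _, removed = remove_outliers(values)
        assert set(removed) == set(idx)

    def test_constant_vector_untouched(self):
        retained, removed = remove_outliers(np.full(100, 3.14))
        assert len(retained) == 100
        assert len(removed) == 0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.arange(10))


class TestJohnsonSUFit:
    def test_unit_su_threshold_closed_form(self):
        rng = np.random.default_rng(2)
        values = johnson_su_sample(rng, (0.0, 1.0, 0.0, 1.0), 100000)
        fit = fit_johnson_su(values)
        assert fit.threshold == pytest.approx(np.sinh(2.3263), rel=0.02)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        values = johnson_su_sample(rng, (-1.0, 1.5, 0.2, 0.1), 20000)
        base = fit_johnson_su(values)
        shifted = fit_johnson_su(values + 5.0)
        assert shifted.xi == pytest.approx(base.xi + 5.0, rel=0.01)
        assert shifted.threshold == pytest.approx(base.threshold + 5.0, rel=0.01)

    def test_normal_limit(self):
        values = np.random.default_rng(3).standard_normal(100000)
        fit = fit_johnson_su(values)
        assert fit.threshold == pytest.approx(2.3263, rel=0.03)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_johnson_su(np.arange(30.0))


class TestCalibrateThreshold:
    LAW = (-1.5, 1.8, 0.04, 0.02)

    def test_background_recovery(self):
        rng = np.random.default_rng(11)
        values = johnson_su_sample(rng, self.LAW, 100000)
        cal = calibrate_threshold(values)
        assert cal.threshold == pytest.approx(johnson_su_quantile(0.99, self.LAW), rel=0.02)

    def test_robust_to_strong_positives(self):
        rng = np.random.default_rng(12)
        values = johnson_su_sample(rng, self.LAW, 50000)
        idx = rng.choice(values.size, size=int(0.05 * values.size), replace=False)
        values[idx] += np.clip(rng.normal(1.0, 0.4, size=idx.size), 0, None)
        cal = calibrate_threshold(values)
        assert cal.threshold == pytest.approx(johnson_su_quantile(0.99, self.LAW), rel=0.05)
        assert len(cal.removed_indices) >= idx.size * 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold([])

    def test_kink_plot_written(self, tmp_path):
        rng = np.random.default_rng(13)
        cal = calibrate_threshold(johnson_su_sample(rng, self.LAW, 5000))
        out = tmp_path / "kink.png"
        cal.plot_kink(str(out))
        assert out.stat().st_size > 0


class TestPercentInhibition:
    def test_control_endpoints(self):
        assert percent_inhibition(1.0, 1.0, 0.2) == 0.0
        assert percent_inhibition(0.2, 1.0, 0.2) == 100.0

    def test_midpoint(self):
        assert percent_inhibition(0.6, 1.0, 0.2) == pytest.approx(50.0)

    def test_inverted_controls_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(0.5, 0.2, 1.0)

    @given(
        st.floats(0.0, 2.0),
        st.floats(1.0, 3.0),
        st.floats(0.0, 0.5),
    )
    def test_linear_in_sample_od(self, sample, pos, neg):
        pct = percent_inhibition(sample, pos + 1.0, neg)
        # linearity: halving the distance to the positive control halves nothing
        midpoint = percent_inhibition((sample + pos + 1.0) / 2, pos + 1.0, neg)
        assert midpoint == pytest.approx(pct / 2, abs=1e-9)


class TestApplyFunnel:
    def test_report_from_printed_counts(self):
        report = FunnelReport.from_counts(
            total_wells=7644, igg_positive=978, fc_binders=139,
            hu_binders=220, cyno_binders=201, mu_binders=56, inhibitors=36,
        )
        assert report.pct("igg_positive") == 12.8
        assert report.pct("hu_binders") == 22.5
        assert report.pct("fc_binders") == 14.2
        assert report.pct("inhibitors") == 16.4

    def test_gates_monotone_on_synthetic_panel(self):
        panel = generate_panel(PanelSimConfig(n_wells=5000, seed=9))
        report = apply_funnel(panel)
        c = report.counts
        assert c["total_wells"] >= c["igg_positive"] >= c["hu_binders"]
        assert c["hu_binders"] >= c["cyno_binders"]
        assert c["hu_binders"] >= c["mu_binders"]
        assert c["hu_binders"] >= c["inhibitors"]
        assert c["igg_positive"] >= c["pcr_eligible"]

    def test_every_percentage_has_audit_pair(self):
        panel = generate_panel(PanelSimConfig(n_wells=2000, seed=10))
        report = apply_funnel(panel)
        assert {"count", "denominator", "denominator_count", "pct"} <= set(
            report.stages.columns
        )
        assert report.stages["pct"].notna().all()

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError, match="od_hu"):
            apply_funnel(pd.DataFrame({"igg_conc": [1.0]}))

    def test_gating_recovers_planted_binders(self):
        config = PanelSimConfig(n_wells=20000, seed=14)
        panel = generate_panel(config)
        thresholds = FunnelConfig()
        report = apply_funnel(panel, thresholds)
        truth_binders = int(
            (panel["true_binder"] & ~panel["true_fc_binder"]
             & (panel["igg_conc"] > thresholds.igg_pos)).sum()
        )
        assert report.counts["hu_binders"] == pytest.approx(truth_binders, rel=0.15)


class TestPercent:
    def test_one_decimal_half_up(self):
        assert percent(139, 978) == 14.2
        assert percent(1, 800) == 0.1  # 0.125 rounds up, not banker's

    def test_integer_rounding(self):
        assert percent(227, 242, decimals=0) == 94

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestThresholdCorrelation:
    def test_perfect_agreement(self):
        x = np.linspace(40, 100, 30)
        rsq, n = threshold_correlation(x, x, cutoff=40)
        assert rsq == pytest.approx(1.0)
        assert n == 30

    def test_sign_blind(self):
        x = np.linspace(40, 100, 30)
        rsq, _ = threshold_correlation(x, -x, cutoff=40)
        assert rsq == pytest.approx(1.0)

    def test_high_cutoff_strengthens_agreement(self):
        # mixture: tight agreement only above 90, noisy below
        rng = np.random.default_rng(17)
        x = rng.uniform(40, 100, 400)
        y = np.where(x > 90, x + rng.normal(0, 2, 400), x + rng.normal(0, 25, 400))
        rsq40, _ = threshold_correlation(x, y, cutoff=40)
        rsq90, _ = threshold_correlation(x, y, cutoff=90)
        assert rsq90 > rsq40

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            threshold_correlation([1, 2, 3], [1, 2, 3], cutoff=2.5)
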