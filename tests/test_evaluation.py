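"""Prediction metrics, relative efficiencies and table aggregation."""

import numpy as np
import pandas as pd
import pytest

from abweight.evaluation import (
    FamilyMetrics,
    aggregate_report,
    compute_re_table,
    mse,
    nrmse,
    pearson_cor,
    relative_efficiency,
)
from abweight.reference import load_reference_metrics, reference_report


class TestMetrics:
    @pytest.mark.parametrize(
        "obs,pred,expected",
        [([1, 2, 3], [1, 2, 3], 0.0), ([2, 4], [2, 2], 2.0), ([0], [3], 9.0)],
    )
    def test_mse_hand_values(self, obs, pred, expected):
        assert mse(np.array(obs, float), np.array(pred, float)) == expected

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.array([1.0]), np.array([1.0, 2.0]))

    @pytest.mark.parametrize(
        "obs,pred,expected",
        [([1, 2, 3], [2, 4, 6], 1.0), ([1, 2, 3], [3, 2, 1], -1.0)],
    )
    def test_pearson_exact_linearity(self, obs, pred, expected):
        assert pearson_cor(np.array(obs, float), np.array(pred, float)) == pytest.approx(expected)

    def test_pearson_zero_variance_is_missing(self):
        assert np.isnan(pearson_cor(np.array([1.0, 2, 3]), np.array([5.0, 5, 5])))

    def test_pearson_short_vector_is_missing(self):
        assert np.isnan(pearson_cor(np.array([1.0, 2]), np.array([2.0, 1])))

    def test_nrmse_hand_value(self):
        assert nrmse(np.array([2.0, 4.0]), np.array([2.0, 2.0])) == pytest.approx(
            0.471405, abs=1e-6
        )

    def test_nrmse_perfect_prediction_is_zero(self):
        assert nrmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0

    def test_nrmse_nonpositive_mean_is_missing_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = nrmse(np.array([-1.0, 1.0]), np.array([0.0, 0.0]))
        assert np.isnan(out)


class TestRelativeEfficiency:
    def test_error_metrics_are_gblup_over_ab(self):
        assert relative_efficiency(119918.048, 114336.072, "mse") == pytest.approx(
            1.049, abs=5e-4
        )
        assert relative_efficiency(2608.669, 1638.615, "mse") == pytest.approx(
            1.592, abs=5e-4
        )

    def test_cor_is_ab_over_gblup(self):
        assert relative_efficiency(0.801, 0.831, "cor") == pytest.approx(
            1.037, abs=5e-4
        )

    def test_equal_performance_gives_one(self):
        for kind in ("mse", "nrmse", "cor"):
            assert relative_efficiency(0.7, 0.7, kind) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            relative_efficiency(1.0, 0.0, "mse")


class TestAggregation:
    def make_metrics(self, vals):
        return [
            FamilyMetrics(family_id=f, mse=m, cor=c, nrmse=r, n_test=10)
            for f, m, c, r in vals
        ]

    def test_af_row_is_mean_of_per_family_res_not_ratio_of_afs(self):
        mg = self.make_metrics([("A", 4.0, 0.5, 0.4), ("B", 1.0, 0.8, 0.2)])
        ma = self.make_metrics([("A", 2.0, 0.6, 0.3), ("B", 1.0, 0.8, 0.2)])
        rep = aggregate_report(mg, ma).table
        af = rep[rep.Family == "AF"].iloc[0]
        # mean of per-family ratios (2.0, 1.0) = 1.5; ratio of means 2.5/1.5 != 1.5
        assert af.RE_MSE == pytest.approx(1.5)
        assert af.MSE_GBLUP == pytest.approx(2.5)

    def test_single_family_af_equals_that_family(self):
        mg = self.make_metrics([("A", 4.0, 0.5, 0.4)])
        ma = self.make_metrics([("A", 2.0, 0.6, 0.3)])
        rep = aggregate_report(mg, ma).table
        assert rep.iloc[0].RE_MSE == rep[rep.Family == "AF"].iloc[0].RE_MSE

    def test_family_set_mismatch_rejected(self):
        mg = self.make_metrics([("A", 1, 0.5, 0.1)])
        ma = self.make_metrics([("B", 1, 0.5, 0.1)])
        with pytest.raises(ValueError, match="differ"):
            aggregate_report(mg, ma)

    def test_missing_cor_excluded_from_cor_average_only(self):
        mg = self.make_metrics([("A", 4.0, np.nan, 0.4), ("B", 1.0, 0.8, 0.2)])
        ma = self.make_metrics([("A", 2.0, np.nan, 0.3), ("B", 1.0, 0.4, 0.2)])
        af = aggregate_report(mg, ma).table.query("Family == 'AF'").iloc[0]
        assert af.MSE_GBLUP == pytest.approx(2.5)
        assert af.COR_GBLUP == pytest.approx(0.8)
        assert af.RE_COR == pytest.approx(0.5)


class TestReferenceTables:
    """The bundled benchmark metric columns reproduce the published
    relative efficiencies and across-family aggregates."""

    def test_af_rows(self):
        expected = {
            "GDM": {"MSE_GBLUP": 132177.698, "RE_MSE": 1.061, "RE_COR": 1.016,
                    "RE_NRMSE": 1.033},
            "Maize_1": {"RE_COR": 1.208, "RE_MSE": 1.315, "RE_NRMSE": 1.126},
            "Maize_2": {"RE_NRMSE": 1.203, "RE_MSE": 1.553, "RE_COR": 1.339},
            "Soybean_4": {"MSE_GBLUP": 138600.854, "RE_MSE": 1.392,
                          "RE_COR": 1.027},
        }
        for name, cols in expected.items():
            af = reference_report(name).rounded().query("Family == 'AF'").iloc[0]
            for col, val in cols.items():
                assert af[col] == pytest.approx(val, abs=5e-4), (name, col)

    def test_per_family_re_values(self):
        expected = [
            ("GDM", "F1", "RE_MSE", 1.049),
            ("GDM", "F6", "RE_COR", 1.037),
            ("Maize_1", "Z006", "RE_MSE", 1.592),
            ("Maize_2", "Z009", "RE_MSE", 2.091),
        ]
        for name, fam, col, val in expected:
            rep = reference_report(name).rounded()
            assert rep.loc[rep.Family == fam, col].item() == pytest.approx(
                val, abs=5e-4
            )

    def test_reference_table_shape(self):
        df = load_reference_metrics()
        assert df.groupby("Data_set").size().to_dict() == {
            "GDM": 13, "Maize_1": 6, "Maize_2": 6, "Soybean_4": 10
        }


def test_plot_re_bars_writes_figure(tmp_path):
    from abweight.evaluation import plot_re_bars

    rep = reference_report("Maize_1")
    out = tmp_path / "re.png"
    plot_re_bars(rep, out)
    assert out.stat().st_size > 0


def test_re_values_scale_invariant():
    """Multiplying phenotypes by c > 0 leaves every RE unchanged."""
    rng = np.random.default_rng(0)
    obs = rng.normal(10, 2, size=20)
    pred_g = obs + rng.normal(0, 1, size=20)
    pred_a = obs + rng.normal(0, 1, size=20)
    c = 7.3
    for kind, fn in [("mse", mse), ("nrmse", nrmse), ("cor", pearson_cor)]:
        re1 = relative_efficiency(fn(obs, pred_g), fn(obs, pred_a), kind)
        re2 = relative_efficiency(fn(c * obs, c * pred_g), fn(c * obs, c * pred_a), kind)
        assert re1 == pytest.approx(re2, rel=1e-10)
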