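"""Shared-slope calibration: regressions, inversion, detection limits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gexpquant.calibration import (
    CalibrationModel,
    DilutionSeries,
    FloorPolicy,
    build_model,
    detection_limit,
    fit_gene,
    quantify,
    read_model,
    write_model,
)
from gexpquant.errors import (
    DegenerateFitError,
    InvalidParameterError,
    UnknownGeneError,
)


def _series_from_lines(lines, concs, noise_sigma=0.0, seed=0):
    """Build a DilutionSeries whose genes follow log10 F = a*log10 R + b."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene_id, (a, b) in lines.items():
        for c in concs:
            log_npa = a * np.log10(c) + b + rng.normal(0.0, noise_sigma)
            rows.append(
                {"gene_id": gene_id, "total_rna_ng": c, "npa": 10.0**log_npa}
            )
    return DilutionSeries(pd.DataFrame(rows))


CONCS = [100.0 / 2**k for k in range(8)]


class TestFitGene:
    def test_exact_line_recovered(self):
        x = np.log10(CONCS)
        y = 0.8 * x + 1.2
        fit = fit_gene(x, y)
        assert fit.slope_a == pytest.approx(0.8)
        assert fit.intercept_b == pytest.approx(1.2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        fit = fit_gene([0.0, 1.0], [2.0, 2.5])
        assert fit.slope_a == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 2

    def test_matches_independent_ols_on_noisy_points(self):
        rng = np.random.default_rng(42)
        x = np.log10(CONCS)
        true_slope = 0.85
        y = true_slope * x + 0.3 + rng.normal(0.0, 0.05, size=len(x))
        fit = fit_gene(x, y)
        oracle = stats.linregress(x, y)
        assert fit.slope_a == pytest.approx(oracle.slope, rel=1e-12)
        assert fit.intercept_b == pytest.approx(oracle.intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(oracle.rvalue**2, rel=1e-9)
        assert abs(fit.slope_a - true_slope) < 3 * oracle.stderr

    def test_identical_abscissae_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gene([2.0, 2.0, 2.0], [1.0, 1.1, 1.2])


class TestBuildModel:
    def test_mean_slope_is_arithmetic_mean(self):
        series = _series_from_lines({"g1": (0.7, 1.0), "g2": (0.9, -0.5)}, CONCS)
        model = build_model(series)
        assert model.mean_slope == pytest.approx(0.8)

    def test_shared_slope_reproduces_intercepts_when_slopes_agree(self):
        series = _series_from_lines({"g1": (0.8, 1.0), "g2": (0.8, -0.4)}, CONCS)
        model = build_model(series)
        assert model.fits["g1"].shared_intercept == pytest.approx(1.0)
        assert model.fits["g2"].shared_intercept == pytest.approx(-0.4)

    def test_single_gene_reduces_to_first_regression(self):
        series = _series_from_lines({"g1": (0.77, 0.2)}, CONCS, noise_sigma=0.03, seed=3)
        model = build_model(series)
        fit = model.fits["g1"]
        assert model.mean_slope == pytest.approx(fit.slope_a)
        assert fit.shared_intercept == pytest.approx(fit.intercept_b)

    def test_shared_intercept_matches_closed_form(self):
        series = _series_from_lines(
            {"g1": (0.7, 1.0), "g2": (0.9, -0.5)}, CONCS, noise_sigma=0.05, seed=1
        )
        model = build_model(series)
        for gene_id, fit in model.fits.items():
            sub = series.data[series.data.gene_id == gene_id]
            x = np.log10(sub.total_rna_ng.to_numpy())
            y = np.log10(sub.npa.to_numpy())
            assert fit.shared_intercept == pytest.approx(
                y.mean() - model.mean_slope * x.mean()
            )

    def test_shared_intercept_minimizes_residuals_at_fixed_slope(self):
        """The closed-form intercept beats a fine grid of alternatives."""
        series = _series_from_lines(
            {"g1": (0.7, 1.0), "g2": (0.9, -0.5), "g3": (0.8, 0.1)},
            CONCS,
            noise_sigma=0.08,
            seed=7,
        )
        model = build_model(series)
        for gene_id, fit in model.fits.items():
            sub = series.data[series.data.gene_id == gene_id]
            x = np.log10(sub.total_rna_ng.to_numpy())
            y = np.log10(sub.npa.to_numpy())

            def rss(b):
                return np.sum((y - (model.mean_slope * x + b)) ** 2)

            best = rss(fit.shared_intercept)
            for b in np.linspace(fit.shared_intercept - 0.5, fit.shared_intercept + 0.5, 201):
                assert best <= rss(b) + 1e-12

    def test_replicate_mean_mode_averages_before_log(self):
        rows = []
        for c in (10.0, 100.0):
            for npa in (1.0, 3.0):  # replicates at each concentration
                rows.append({"gene_id": "g", "total_rna_ng": c, "npa": npa * c / 10.0})
        series = DilutionSeries(pd.DataFrame(rows))
        model = build_model(series, replicate_mode="means")
        # mean NPA per concentration: 2.0 and 20.0 -> exact slope 1 line
        assert model.mean_slope == pytest.approx(1.0)
        assert model.fits["g"].r_squared == pytest.approx(1.0)

    def test_unfittable_gene_fails_build_naming_it(self):
        frame = pd.concat(
            [
                _series_from_lines({"good": (0.8, 0.0)}, CONCS).data,
                pd.DataFrame(
                    [{"gene_id": "bad", "total_rna_ng": c, "npa": -1.0} for c in CONCS]
                ),
            ],
            ignore_index=True,
        )
        with pytest.raises(DegenerateFitError, match="bad"):
            build_model(DilutionSeries(frame))

    def test_parallelism_diagnostic_shrinks_with_noise(self):
        lines = {f"g{i}": (0.8, 0.1 * i) for i in range(6)}
        tight = build_model(_series_from_lines(lines, CONCS, 0.02, seed=5))
        loose = build_model(_series_from_lines(lines, CONCS, 0.2, seed=5))
        assert tight.max_abs_slope_dev < loose.max_abs_slope_dev


class TestQuantify:
    @pytest.fixture
    def model(self):
        series = _series_from_lines({"g1": (0.8, 1.2)}, CONCS)
        return build_model(series, floor_policy=FloorPolicy(fixed_npa=1e-4))

    def test_npa_at_intercept_maps_to_unit_amount(self, model):
        b = model.fits["g1"].shared_intercept
        rows = pd.DataFrame([{"gene_id": "g1", "npa": 10.0**b}])
        out = quantify(rows, model)
        assert out.rel_amount.iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("log_r", [-2.0, 0.0, 1.7])
    def test_inverse_identity_roundtrip(self, model, log_r):
        b = model.fits["g1"].shared_intercept
        npa = 10.0 ** (model.mean_slope * log_r + b)
        out = quantify(pd.DataFrame([{"gene_id": "g1", "npa": npa}]), model)
        assert out.rel_amount.iloc[0] == pytest.approx(10.0**log_r)

    def test_below_floor_reports_limit_value(self, model):
        floor = model.detection_limits["g1"][0]
        out = quantify(pd.DataFrame([{"gene_id": "g1", "npa": floor / 10}]), model)
        assert bool(out.below_limit.iloc[0])
        assert out.rel_amount.iloc[0] == pytest.approx(model.detection_limits["g1"][1])

    def test_missing_npa_flagged_not_zero(self, model):
        out = quantify(pd.DataFrame([{"gene_id": "g1", "npa": np.nan}]), model)
        assert bool(out.below_limit.iloc[0])

    def test_unknown_gene_raises(self, model):
        with pytest.raises(UnknownGeneError):
            quantify(pd.DataFrame([{"gene_id": "nope", "npa": 1.0}]), model)


class TestDetectionLimit:
    @pytest.fixture
    def model(self):
        return build_model(_series_from_lines({"g1": (0.8, 1.2), "g2": (0.8, -0.3)}, CONCS))

    def test_limit_is_line_inversion_of_floor(self, model):
        floor = 1e-3
        limits = detection_limit(model, floor)
        for g in ("g1", "g2"):
            b = model.fits[g].shared_intercept
            expected = 10.0 ** ((np.log10(floor) - b) / model.mean_slope)
            assert limits[g] == pytest.approx(expected)

    def test_doubling_floor_scales_limit_by_two_to_inverse_slope(self, model):
        l1 = detection_limit(model, 1e-3)
        l2 = detection_limit(model, 2e-3)
        for g in l1:
            assert l2[g] / l1[g] == pytest.approx(2.0 ** (1.0 / model.mean_slope))

    def test_halving_spike_area_doubles_area_based_floor(self):
        policy = FloorPolicy(min_peak_area=50.0)
        assert policy.npa_floor(500.0) == pytest.approx(2 * policy.npa_floor(1000.0))

    def test_non_positive_floor_rejected(self, model):
        with pytest.raises(InvalidParameterError):
            detection_limit(model, 0.0)


class TestModelSerialization:
    def test_roundtrip_preserves_all_numbers(self, tmp_path):
        series = _series_from_lines(
            {"g1": (0.7, 1.0), "g2": (0.9, -0.5)}, CONCS, noise_sigma=0.05, seed=2
        )
        model = build_model(series, floor_policy=FloorPolicy(fixed_npa=1e-4))
        model.provenance["kit"] = "lot42"
        path = tmp_path / "model.tsv"
        write_model(model, path)
        back = read_model(path)
        assert back.mean_slope == model.mean_slope
        assert back.replicate_mode == model.replicate_mode
        assert back.provenance["kit"] == "lot42"
        for g, fit in model.fits.items():
            bfit = back.fits[g]
            assert bfit.slope_a == fit.slope_a
            assert bfit.intercept_b == fit.intercept_b
            assert bfit.shared_intercept == fit.shared_intercept
            assert bfit.r_squared == fit.r_squared
        assert back.detection_limits == model.detection_limits
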