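"""Refraction arithmetic, summary statistics and power-law fitting tests."""

import numpy as np
import pandas as pd
import pytest

from sbsim.optics import (
    FitError,
    OpticsConfig,
    TighteningFit,
    evaluate_fit,
    eye_power,
    fit_power_law,
    load_reference_cases,
    myopic_change,
    relative_increment,
    round_reported,
    summarize_by_bandwidth,
)


class TestEyePower:
    def test_zero_lens_power(self):
        assert eye_power(OpticsConfig(D1=44.0, D2=0.0, d=5.0)) == pytest.approx(44.0)

    def test_zero_separation(self):
        assert eye_power(OpticsConfig(D1=44.0, D2=20.0, d=0.0)) == pytest.approx(64.0)

    def test_thick_lens_formula(self):
        # 44 + 20 - 44*20*0.0056/1.336, scalar arithmetic oracle
        assert eye_power(OpticsConfig(D1=44.0, D2=20.0, d=5.6)) == pytest.approx(60.311, abs=5e-4)

    def test_requires_components(self):
        with pytest.raises(ValueError):
            eye_power(OpticsConfig())

    def test_refractive_index_validated(self):
        with pytest.raises(ValueError):
            OpticsConfig(n1=0.9)


class TestMyopicChange:
    def test_no_elongation_no_shift(self):
        assert myopic_change(24.860, 24.860) == 0.0

    def test_case1_value(self):
        assert round_reported(myopic_change(24.860, 25.382)) == pytest.approx(-1.11)

    def test_elongation_is_myopic(self):
        assert myopic_change(24.0, 24.5) < 0.0

    def test_strictly_decreasing_in_postop_length(self):
        vals = [myopic_change(24.860, al) for al in np.linspace(24.860, 25.5, 30)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            myopic_change(-1.0, 25.0)

    def test_rounding_half_away_from_zero(self):
        assert round_reported(-0.005, 2) == -0.01
        assert round_reported(0.125, 2) == 0.13
        assert round_reported(-1.114999, 2) == -1.11


class TestSummaries:
    def test_reference_bandwidth_means(self):
        """Mean dAL/dD per band width from the bundled nine-case table."""
        df = load_reference_cases().rename(columns={"dD100_D": "dD_D"})
        s = summarize_by_bandwidth(df[["bandwidth_mm", "dAL_mm", "dD_D"]])
        assert s.loc[2.5, "mean_dAL_mm"] == pytest.approx(0.51, abs=5e-3)
        assert s.loc[2.5, "mean_dD_D"] == pytest.approx(-1.07, abs=5e-3)
        assert s.loc[1.0, "mean_dD_D"] == pytest.approx(-0.44, abs=5e-3)
        assert s.loc[1.0, "sd_dD_D"] == pytest.approx(0.15, abs=5e-3)

    def test_identical_triplicates_have_zero_sd(self):
        df = pd.DataFrame({"bandwidth_mm": [2.0] * 3, "dAL_mm": [0.4] * 3})
        s = summarize_by_bandwidth(df)
        assert s.loc[2.0, "sd_dAL_mm"] == pytest.approx(0.0)

    def test_requires_outcome_columns(self):
        with pytest.raises(ValueError):
            summarize_by_bandwidth(pd.DataFrame({"bandwidth_mm": [1.0]}))


class TestPowerLaw:
    TRUE = TighteningFit(a=-1.051e-6, b=2.96, c=-0.1972, rmse=0.0)
    X = np.array([33.0, 67.0, 100.0])

    def _clean_data(self):
        return np.array([evaluate_fit(self.TRUE, x) for x in self.X])

    def test_noiseless_identifiability(self):
        fit = fit_power_law(self.X, self._clean_data())
        assert fit.a == pytest.approx(self.TRUE.a, rel=1e-6)
        assert fit.b == pytest.approx(self.TRUE.b, rel=1e-6)
        assert fit.c == pytest.approx(self.TRUE.c, rel=1e-6)

    def test_three_point_fit_interpolates(self):
        df = load_reference_cases()
        y = df[df.bandwidth_mm == 2.5][["dD33_D", "dD67_D", "dD100_D"]].mean().to_numpy()
        fit = fit_power_law(self.X, y)
        assert fit.rmse < 0.05
        assert fit.b > 0.0

    def test_constant_offset_moves_only_c(self):
        y = self._clean_data()
        f0 = fit_power_law(self.X, y)
        f1 = fit_power_law(self.X, y + 0.25)
        assert f1.a == pytest.approx(f0.a, rel=1e-5)
        assert f1.b == pytest.approx(f0.b, rel=1e-5)
        assert f1.c - f0.c == pytest.approx(0.25, abs=1e-6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(FitError):
            fit_power_law([33.0, 33.0, 33.0], [-0.1, -0.2, -0.3])
        with pytest.raises(FitError):
            fit_power_law([33.0, 67.0], [-0.1, -0.2])

    def test_evaluate_at_zero_gives_offset(self):
        assert evaluate_fit(self.TRUE, 0.0) == pytest.approx(self.TRUE.c)

    def test_noisy_parameter_recovery(self):
        """Median |b_hat - b| < 0.3 over 200 seeded noisy replicates (sigma = 0.02 D)."""
        rng = np.random.default_rng(2024)
        y = self._clean_data()
        errs = []
        for _ in range(200):
            fit = fit_power_law(self.X, y + rng.normal(0.0, 0.02, 3))
            errs.append(abs(fit.b - self.TRUE.b))
        assert np.median(errs) < 0.3


class TestRelativeIncrement:
    def test_published_increment(self):
        assert relative_increment(-0.44, -1.04) == pytest.approx(136.0, abs=0.5)

    def test_no_change(self):
        assert relative_increment(-0.5, -0.5) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_increment(0.0, -1.0)
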