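import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shelfkin import (
    DEFAULT_CONSTANTS,
    DomainError,
    GibbsTempFit,
    PairingError,
    SensoryFit,
    ShelfLifeModel,
    StorageSeries,
    fit_sensory_regression,
    predict_sensory,
    rate_from_gibbs,
    select_key_index,
    solve_shelf_life,
    validate_predictions,
)

# published sensory link and dG*(T) fit for the sedimentation-rate index
CSR_SENSORY = SensoryFit("CSR", -9.6927, 96.131, 0.9868)
CSR_GIBBS = GibbsTempFit(0.1467, 37.398, 0.9918)


@pytest.fixture
def csr_model():
    return ShelfLifeModel(sensory=CSR_SENSORY, gibbs=CSR_GIBBS, C0=0.82)


def _series(index_name, temperature, times, values):
    return StorageSeries(index_name, temperature, np.asarray(times, float),
                         np.asarray(values, float))


class TestSensoryRegression:
    def test_exact_linear_link_recovery(self):
        """Pairs generated exactly from SS = -9.6927 C + 96.131 across two
        temperatures recover the coefficients exactly."""
        idx, sens = [], []
        for T, k in [(298.15, 0.0367), (308.15, 0.0678)]:
            t = np.arange(0.0, 22.0, 2.0)
            c = 0.82 * np.exp(k * t)
            idx.append(_series("CSR", T, t, c))
            sens.append(_series("sensory_score", T, t, -9.6927 * c + 96.131))
        fit = fit_sensory_regression(sens, idx)
        assert fit.slope == pytest.approx(-9.6927, rel=1e-9)
        assert fit.intercept == pytest.approx(96.131, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.index_name == "CSR"

    def test_constant_score_gives_zero_slope(self):
        t = np.arange(0.0, 8.0, 2.0)
        idx = _series("CSR", 298.15, t, 0.82 * np.exp(0.1 * t))
        sens = _series("sensory_score", 298.15, t, np.full_like(t, 90.0))
        fit = fit_sensory_regression(sens, idx)
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_noisy_viscosity_link_recovery(self):
        """Additive noise sigma = 0.5 on 40 pairs: slope within 5 % of truth."""
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 40.0)
        eta = 5.82 * np.exp(-0.02 * t)
        ss = 10.322 * eta - 28.007 + rng.normal(0.0, 0.5, len(t))
        fit = fit_sensory_regression(
            _series("sensory_score", 298.15, t, ss), _series("viscosity", 298.15, t, eta)
        )
        assert fit.slope == pytest.approx(10.322, rel=0.05)

    def test_mismatched_support_rejected(self):
        idx = _series("CSR", 298.15, [0.0, 2.0, 4.0], [0.82, 0.9, 1.0])
        sens = _series("sensory_score", 308.15, [0.0, 2.0, 4.0], [88.0, 87.0, 86.0])
        with pytest.raises(PairingError, match="disagree"):
            fit_sensory_regression(sens, idx)


class TestSelectKeyIndex:
    def test_highest_r_squared_wins(self):
        fits = [
            SensoryFit("CSR", -9.6927, 96.131, 0.9868),
            SensoryFit("particle_size", -33.187, 105.79, 0.9796),
            SensoryFit("viscosity", 10.322, -28.007, 0.9558),
        ]
        assert select_key_index(fits).index_name == "CSR"

    def test_single_candidate(self):
        only = SensoryFit("viscosity", 10.322, -28.007, 0.9558)
        assert select_key_index([only]) is only

    def test_tie_breaks_lexicographically(self):
        fits = [SensoryFit("b", -1.0, 90.0, 0.9), SensoryFit("a", -1.0, 90.0, 0.9)]
        assert select_key_index(fits).index_name == "a"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_key_index([])


class TestRateFromGibbs:
    def test_closed_form_hand_evaluation(self, csr_model):
        """Independent evaluation of (kb T/h) exp(-dG/(RT)) for the CSR fit."""
        c = DEFAULT_CONSTANTS
        T = 298.15
        dG_J = 1000.0 * (0.1467 * T + 37.398)
        expected = (c.k_b * T / c.h_planck) * np.exp(-dG_J / (c.R_gas * T))
        k = rate_from_gibbs(csr_model, T)
        assert k == pytest.approx(expected, rel=1e-12)
        assert k == pytest.approx(0.0378, abs=2e-4)

    def test_no_barrier_limit(self):
        model = ShelfLifeModel(sensory=CSR_SENSORY, gibbs=GibbsTempFit(0.0, 0.0, 1.0), C0=0.82)
        c = DEFAULT_CONSTANTS
        T = 300.0
        assert rate_from_gibbs(model, T) == pytest.approx(c.k_b * T / c.h_planck, rel=1e-12)

    def test_rate_increases_with_temperature(self, csr_model):
        grid = np.linspace(298.0, 328.0, 121)
        rates = [rate_from_gibbs(csr_model, T) for T in grid]
        assert np.all(np.diff(rates) > 0)


class TestPredictAndSolve:
    def test_initial_score_closed_form(self, csr_model):
        ss0 = predict_sensory(csr_model, 0.0, 298.15)
        assert ss0 == pytest.approx(96.131 - 9.6927 * 0.82, rel=1e-12)
        assert ss0 == pytest.approx(88.18, abs=0.01)

    def test_score_declines_with_time(self, csr_model):
        times = np.linspace(0.0, 60.0, 31)
        scores = [predict_sensory(csr_model, t, 308.15) for t in times]
        assert np.all(np.diff(scores) < 0)

    def test_shelf_life_near_19_days_at_25C(self, csr_model):
        t = solve_shelf_life(csr_model, 298.15)
        assert t == pytest.approx(18.7, abs=0.1)

    def test_threshold_equal_to_initial_score_gives_zero(self):
        model = ShelfLifeModel(
            sensory=CSR_SENSORY, gibbs=CSR_GIBBS, C0=0.82,
            threshold=96.131 - 9.6927 * 0.82,
        )
        assert solve_shelf_life(model, 298.15) == pytest.approx(0.0, abs=1e-12)

    def test_threshold_above_initial_score_rejected(self):
        model = ShelfLifeModel(sensory=CSR_SENSORY, gibbs=CSR_GIBBS, C0=0.82, threshold=90.0)
        with pytest.raises(DomainError, match="initial sensory score"):
            solve_shelf_life(model, 298.15)

    def test_shelf_life_non_increasing_in_temperature(self, csr_model):
        grid = np.linspace(298.15, 328.15, 61)
        lives = [solve_shelf_life(csr_model, T) for T in grid]
        assert np.all(np.diff(lives) < 0)
        assert solve_shelf_life(csr_model, 318.15) < solve_shelf_life(csr_model, 298.15)

    @given(
        slope=st.floats(-50.0, -0.5),
        intercept=st.floats(85.0, 110.0),
        c0=st.floats(0.1, 2.0),
        threshold=st.floats(40.0, 80.0),
        T=st.floats(280.0, 340.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_returns_threshold(self, slope, intercept, c0, threshold, T):
        """predict_sensory at the solved shelf life must return the threshold."""
        if slope * c0 + intercept <= threshold:
            return  # unacceptable at t = 0; covered by the domain-error test
        model = ShelfLifeModel(
            sensory=SensoryFit("CSR", slope, intercept, 1.0),
            gibbs=CSR_GIBBS, C0=c0, threshold=threshold,
        )
        t = solve_shelf_life(model, T)
        assert predict_sensory(model, t, T) == pytest.approx(threshold, abs=1e-9)

    def test_decaying_index_model(self):
        """A viscosity-style model (index decays, sensory slope positive) solves too."""
        model = ShelfLifeModel(
            sensory=SensoryFit("viscosity", 10.322, -28.007, 0.9558),
            gibbs=GibbsTempFit(0.4513, -53.788, 0.8951),
            C0=5.82, threshold=20.0, direction=-1,
        )
        t = solve_shelf_life(model, 298.15)
        assert t > 0
        assert predict_sensory(model, t, 298.15) == pytest.approx(20.0, abs=1e-9)

    def test_unsolvable_direction_combination_rejected(self):
        with pytest.raises(DomainError, match="decline"):
            ShelfLifeModel(
                sensory=SensoryFit("viscosity", 10.322, -28.007, 0.9558),
                gibbs=CSR_GIBBS, C0=5.82, direction=1,
            )


class TestValidatePredictions:
    def test_perfect_prediction(self):
        stats = validate_predictions([90.0, 120.0, 150.0], [90.0, 120.0, 150.0], 1)
        assert stats.Se == 0.0 and stats.Ve == 0.0 and stats.acceptable

    def test_hand_arithmetic(self):
        """Residuals (10, 10, -10), one predictor: Se = sqrt(300), Ve = Se/120."""
        stats = validate_predictions([90.0, 120.0, 150.0], [80.0, 110.0, 160.0], 1)
        assert stats.Se == pytest.approx(np.sqrt(300.0), rel=1e-12)
        assert stats.Ve == pytest.approx(100.0 * np.sqrt(300.0) / 120.0, rel=1e-12)
        assert stats.acceptable  # 14.43 % < 15 %

    def test_zero_degrees_of_freedom_rejected(self):
        with pytest.raises(DomainError, match="degrees of freedom"):
            validate_predictions([90.0, 120.0, 150.0], [80.0, 110.0, 160.0], 2)
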