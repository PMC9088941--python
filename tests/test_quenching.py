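"""Stern-Volmer / double-log fitting and mechanism classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind.errors import ValidationError
from quenchbind.quenching import (
    QuenchFit,
    TitrationSeries,
    _fit_line,
    classify_mechanism,
    double_log_fit,
    quench_ratios,
    stern_volmer_fit,
)
from quenchbind.synthetic import QuenchSimSpec, simulate_titration

from conftest import KSV_BY_T, TAU0_NS


def _series(ksv=4.142e4, ka=8.978e4, n=1.0, law="stern_volmer", noise=0.0,
            seed=0, temperature=298.0):
    spec = QuenchSimSpec(ksv_true=ksv, ka_true=ka, n_true=n, noise_sd=noise,
                         seed=seed)
    return simulate_titration(spec, temperature, law=law)


class TestQuenchRatios:
    def test_noiseless_ratios_equal_stern_volmer_prediction(self):
        series = _series()
        ratios = quench_ratios(series)
        for q, r in ratios:
            assert r == pytest.approx(1.0 + 4.142e4 * q, abs=1e-12)

    def test_zero_concentration_anchor_is_exactly_one(self):
        assert quench_ratios(_series())[0] == (0.0, 1.0)

    def test_identical_spectra_give_unit_ratios(self):
        series = _series()
        flat = TitrationSeries(
            temperature=298.0,
            quencher_concs=series.quencher_concs,
            wavelengths=series.wavelengths,
            intensities=np.tile(series.intensities[0], (7, 1)),
        )
        assert all(r == pytest.approx(1.0) for _, r in quench_ratios(flat))

    def test_invariant_under_uniform_rescaling(self):
        series = _series(noise=0.01, seed=3)
        scaled = TitrationSeries(
            temperature=series.temperature,
            quencher_concs=series.quencher_concs,
            wavelengths=series.wavelengths,
            intensities=series.intensities * 17.3,
        )
        r1 = [r for _, r in quench_ratios(series)]
        r2 = [r for _, r in quench_ratios(scaled)]
        assert np.allclose(r1, r2, rtol=1e-12)

    @pytest.mark.parametrize("mode", ["fixed", "peak", "integrated", 345.0])
    def test_all_modes_agree_on_shiftless_noiseless_data(self, mode):
        ratios = quench_ratios(_series(), mode=mode)
        for q, r in ratios:
            assert r == pytest.approx(1.0 + 4.142e4 * q, rel=1e-9)

    def test_nonpositive_intensity_names_the_concentration(self):
        series = _series()
        bad = series.intensities.copy()
        bad[3, :] = 0.0
        broken = TitrationSeries(
            temperature=298.0, quencher_concs=series.quencher_concs,
            wavelengths=series.wavelengths, intensities=bad,
        )
        with pytest.raises(ValidationError, match="1.2e-05"):
            quench_ratios(broken)


class TestSternVolmer:
    def test_slope_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        q = np.linspace(0, 2.4e-5, 7)
        y = 1 + 3e4 * q + rng.normal(0, 0.01, q.size)
        fit = stern_volmer_fit(list(zip(q, y)), temperature=298.0)
        # independent closed-form OLS
        A = np.column_stack([q, np.ones_like(q)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.ksv == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_noiseless_fit_has_unit_intercept_and_r_squared(self):
        fit = stern_volmer_fit(quench_ratios(_series()), 298.0)
        assert fit.ksv == pytest.approx(4.142e4, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_kq_converts_tau0_from_ns_to_seconds(self):
        fit = stern_volmer_fit(quench_ratios(_series()), 298.0, tau0_ns=TAU0_NS)
        assert fit.kq == pytest.approx(4.142e4 / (TAU0_NS * 1e-9), rel=1e-9)

    def test_flat_ratios_give_zero_slope(self):
        fit = stern_volmer_fit([(0, 1.0), (1e-5, 1.0), (2e-5, 1.0)], 298.0)
        assert fit.ksv == pytest.approx(0.0, abs=1e-12)

    def test_two_point_line_via_internal_helper(self):
        slope, intercept, r2, _ = _fit_line(np.array([1.0, 3.0]),
                                            np.array([2.0, 8.0]))
        assert (slope, intercept, r2) == (3.0, -1.0, 1.0)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValidationError):
            stern_volmer_fit([(0, 1.0), (1e-5, 1.4)], 298.0)

    def test_noise_recovery_median_under_three_percent(self):
        errs = []
        for seed in range(20):
            ratios = quench_ratios(_series(noise=0.01, seed=seed))
            fit = stern_volmer_fit(ratios, 298.0)
            errs.append(abs(fit.ksv / 4.142e4 - 1.0))
        assert np.median(errs) < 0.03


class TestDoubleLog:
    def test_roundtrip_recovers_ka_and_n(self):
        ratios = quench_ratios(_series(ka=8.978e4, n=1.073, law="double_log"))
        fit = double_log_fit(ratios, 298.0)
        assert fit.ka == pytest.approx(8.978e4, rel=1e-3)
        assert fit.n == pytest.approx(1.073, abs=1e-3)

    def test_stern_volmer_data_yields_unit_site_number(self):
        # with n = 1 the two laws coincide: fitted Ka = Ksv, n = 1
        ratios = quench_ratios(_series(ksv=5e4))
        fit = double_log_fit(ratios, 298.0)
        assert fit.n == pytest.approx(1.0, abs=1e-9)
        assert fit.ka == pytest.approx(5e4, rel=1e-9)

    def test_identity_line_gives_unit_constants(self):
        q = np.array([0.1, 0.2, 0.5, 1.0])
        ratios = [(0.0, 1.0)] + [(qi, 1.0 + qi) for qi in q]
        fit = double_log_fit(ratios, 298.0)
        assert fit.log_ka_intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.ka == pytest.approx(1.0, rel=1e-12)
        assert fit.n == pytest.approx(1.0, abs=1e-12)

    def test_unquenched_points_dropped_with_warning(self):
        ratios = [(0.0, 1.0), (1e-6, 0.99), (2e-6, 1.5), (3e-6, 1.8),
                  (4e-6, 2.1)]
        with pytest.warns(UserWarning, match="F >= F0"):
            fit = double_log_fit(ratios, 298.0)
        assert fit.ka > 0

    def test_too_few_surviving_points_rejected(self):
        with pytest.raises(ValidationError):
            double_log_fit([(0.0, 1.0), (1e-6, 1.2), (2e-6, 1.4)], 298.0)


class TestMechanism:
    @staticmethod
    def _fit(temp, ksv, kq=None):
        return QuenchFit(ksv=ksv, ksv_stderr=0.0, intercept=1.0,
                         r_squared=1.0, temperature=temp, kq=kq)

    def test_reference_system_is_static(self):
        fits = [self._fit(t, KSV_BY_T[t]) for t in sorted(KSV_BY_T)]
        fits[0] = self._fit(298.0, KSV_BY_T[298.0], kq=8.835e12)
        call = classify_mechanism(fits, lifetime_invariant=True)
        assert call.label == "static"
        assert len(call.evidence) == 3

    def test_mirrored_criteria_vote_dynamic(self):
        fits = [self._fit(298.0, 2.0e4, kq=5e9), self._fit(304.0, 3.0e4),
                self._fit(310.0, 4.0e4)]
        call = classify_mechanism(fits, lifetime_invariant=False)
        assert call.label == "dynamic"

    def test_one_versus_one_split_is_inconclusive(self):
        # Ksv decreasing (static) but Kq below the diffusion ceiling
        # (dynamic), no lifetime data: a 1-1 split must not be labelled.
        fits = [self._fit(298.0, 4.0e4, kq=5e9), self._fit(304.0, 3.0e4),
                self._fit(310.0, 2.0e4)]
        call = classify_mechanism(fits)
        assert call.label == "inconclusive"

    def test_duplicate_temperatures_rejected(self):
        fits = [self._fit(298.0, 4e4), self._fit(298.0, 3e4)]
        with pytest.raises(ValidationError):
            classify_mechanism(fits)

    def test_single_temperature_rejected(self):
        with pytest.raises(ValidationError):
            classify_mechanism([self._fit(298.0, 4e4)])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=50),
)
def test_ratio_scale_invariance_property(scale, seed):
    """F0/F is a ratio: multiplying every spectrum by one constant cannot
    change it."""
    series = _series(noise=0.02, seed=seed)
    scaled = TitrationSeries(
        temperature=series.temperature,
        quencher_concs=series.quencher_concs,
        wavelengths=series.wavelengths,
        intensities=series.intensities * scale,
    )
    a = np.array([r for _, r in quench_ratios(series)])
    b = np.array([r for _, r in quench_ratios(scaled)])
    assert np.allclose(a, b, rtol=1e-9)
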