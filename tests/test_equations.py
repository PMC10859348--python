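import json

import numpy as np
import pytest

from cochleagen.equations import (
    ANGLE_PARAMETERS,
    PARAMETER_NAMES,
    CochlearAngle,
    EquationRegistry,
    ExtrapolationError,
    NormalisationContext,
    ParameterEquation,
    default_registry,
    default_sweep_range,
    denormalize,
    evaluate_equation,
    parameter_set,
)


class TestEvaluateEquation:
    @pytest.mark.parametrize(
        "name, theta, expected",
        [
            ("Wsm", 0.0, 0.074),          # linear intercept
            ("alpha", 250.0, 0.21193),    # Gaussian peak: 0.11423 + 0.0977
            ("Hsg", 338.28, 0.0425),      # centred polynomial at its centre
            ("Bm", 0.0, 0.157),           # linear intercept
        ],
    )
    def test_spot_values(self, name, theta, expected):
        reg = default_registry()
        assert evaluate_equation(reg[name], theta) == pytest.approx(expected, abs=1e-12)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ParameterEquation("x", "sinusoid", (1.0, 2.0))

    def test_centring_only_for_polynomials(self):
        with pytest.raises(ValueError, match="centring"):
            ParameterEquation("x", "linear", (1.0, 2.0), centring=(0.0, 1.0))
        with pytest.raises(ValueError, match="centring"):
            ParameterEquation("x", "polynomial", (1.0, 2.0, 3.0))

    def test_centred_polynomial_matches_naive_power_sum(self):
        # oracle: evaluate the polynomial as an explicit power sum in the
        # centred variable
        reg = default_registry()
        for name in ("Hsg", "Ft", "Wc", "beta"):
            eq = reg[name]
            c1, c2 = eq.centring
            coeffs = eq.coefficients
            for theta in np.linspace(0.0, 720.0, 41):
                tn = (theta - c1) / c2
                naive = sum(
                    c * tn ** (len(coeffs) - 1 - i) for i, c in enumerate(coeffs)
                )
                assert evaluate_equation(eq, theta) == pytest.approx(naive, abs=1e-12)

    def test_dense_grid_finite(self):
        grid = np.linspace(0.0, 720.0, 721)
        for eq in default_registry():
            vals = np.asarray(eq(grid))
            assert np.all(np.isfinite(vals)), eq.name

    def test_alpha_consistent_with_published_angle_range(self):
        # the lamina angle stays within (0.0977, 0.2120] rad, i.e. the
        # 0-15 degree interval quoted for the measured data
        eq = default_registry()["alpha"]
        vals = np.asarray(eq(np.linspace(0.0, 720.0, 1441)))
        assert vals.min() > 0.0977
        assert vals.max() <= 0.2120


class TestParameterSet:
    def test_contains_expected_values_and_is_deterministic(self):
        ps1 = parameter_set(0.0)
        ps2 = parameter_set(0.0)
        assert ps1.Bm == pytest.approx(0.157, abs=1e-12)
        assert ps1.as_dict() == ps2.as_dict()

    def test_all_sixteen_parameters_present(self):
        ps = parameter_set(123.4)
        assert set(ps.as_dict()) == set(PARAMETER_NAMES)

    def test_extrapolation_guard(self):
        with pytest.raises(ExtrapolationError):
            parameter_set(800.0)
        with pytest.warns(UserWarning, match="extrapolat"):
            ps = parameter_set(CochlearAngle(800.0, extrapolate=True))
        assert np.isfinite(ps.alpha)

    def test_invariant_violation_reported_not_clamped(self):
        # substitute a Wm curve that dips below Wsl: the set must carry the
        # violation and keep the raw value
        bad = default_registry().replace(
            ParameterEquation("Wm", "linear", (0.0, 0.001))
        )
        with pytest.warns(UserWarning, match="Wsl"):
            ps = parameter_set(0.0, registry=bad)
        assert ps.Wm == pytest.approx(0.001)
        assert any("Wsl" in w for w in ps.warnings_)


class TestDenormalize:
    def test_unit_width_is_identity(self):
        ps = parameter_set(0.0)
        mm = denormalize(ps, NormalisationContext(1.0))
        for name in PARAMETER_NAMES:
            assert mm[name] == pytest.approx(ps[name])

    def test_lengths_scale_angles_do_not(self):
        ps = parameter_set(0.0).with_value("Wsl", 0.2)
        mm = denormalize(ps, NormalisationContext(2.0))
        assert mm.Wsl == pytest.approx(0.4)
        assert mm.alpha == pytest.approx(ps.alpha)
        assert mm.beta == pytest.approx(ps.beta)

    def test_composition_equals_product_width(self):
        ps = parameter_set(90.0)
        ab = denormalize(denormalize(ps, NormalisationContext(1.5)),
                         NormalisationContext(2.0))
        direct = denormalize(ps, NormalisationContext(3.0))
        for name in PARAMETER_NAMES:
            assert ab[name] == pytest.approx(direct[name], rel=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            NormalisationContext(0.0)
        with pytest.raises(ValueError):
            NormalisationContext(-1.0)


class TestSweepRanges:
    def test_alpha_range_is_zero_to_fifteen_degrees(self):
        lo, hi = default_sweep_range("alpha", 0.0)
        assert lo == 0.0
        assert hi == pytest.approx(np.radians(15.0), abs=1e-4)

    def test_wm_floor_sits_at_the_ligament_width(self):
        reg = default_registry()
        for theta in (0.0, 360.0):
            lo, hi = default_sweep_range(
                "Wm", theta, ctx=NormalisationContext(2.0)
            )
            wsl = evaluate_equation(reg["Wsl"], theta)
            assert wsl <= lo <= 1.1 * wsl
            assert hi == pytest.approx(0.3)

    def test_fraction_mode_is_plus_minus_twenty_percent(self):
        lo, hi = default_sweep_range("Bm", 0.0, mode="fraction")
        assert (lo, hi) == pytest.approx((0.1256, 0.1884))

    def test_percentile_mode_spans_curve_variation(self):
        lo, hi = default_sweep_range("Wa", 0.0)
        assert lo < hi < 0.0  # Wa is negative over the whole range
        assert hi - lo > 0.05  # the curve's dynamic range, not a sliver

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            default_sweep_range("nonesuch", 0.0)


class TestRegistrySerialisation:
    def test_json_round_trip(self, tmp_path):
        reg = default_registry()
        path = tmp_path / "registry.json"
        reg.to_json(path)
        back = EquationRegistry.from_json(str(path))
        grid = np.linspace(0.0, 720.0, 73)
        for eq in reg:
            np.testing.assert_allclose(eq(grid), back[eq.name](grid), rtol=0)

    def test_replace_substitutes_a_curve(self):
        reg = default_registry().replace(
            ParameterEquation("Bm", "linear", (0.0, 0.2))
        )
        assert evaluate_equation(reg["Bm"], 500.0) == pytest.approx(0.2)

    def test_duplicate_names_rejected(self):
        eq = ParameterEquation("Bm", "linear", (0.0, 0.2))
        with pytest.raises(ValueError, match="duplicate"):
            EquationRegistry([eq, eq])
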