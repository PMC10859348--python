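import warnings

import numpy as np
import pytest

from cochleagen.fem import (
    FemConfig,
    FemError,
    SensitivityResult,
    build_domain,
    fibre_potential_profile,
    make_problem,
    rank_parameters,
    solve_stationary,
    sweep_parameter,
)
from cochleagen.meshing import DomainSpec, InterfaceSpec, build_mesh

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
TOP_EDGE = np.array([[0.0, 1.0], [1.0, 1.0]])


def square_spec(h=0.08, interfaces=()):
    return DomainSpec(
        outer=UNIT_SQUARE,
        background_name="medium",
        background_conductivity=1.0,
        background_h=h,
        interfaces=list(interfaces),
        source_arcs=[TOP_EDGE],
    )


@pytest.fixture(scope="module")
def square_solution():
    mesh = build_mesh(square_spec())
    return solve_stationary(make_problem(mesh, {}, 2e-3))


class TestStationarySolve:
    def test_uniform_square_matches_1d_closed_form(self, square_solution):
        # 2 mA over a 1 mm wide, 1 mm tall slab of sigma = 1 S/m:
        # V(y) = (I / width) * y / sigma = 2 * y_m volts
        for y in (0.25, 0.5, 0.75, 0.999):
            v = square_solution.potential_at([0.37, y])
            assert v == pytest.approx(2.0 * y * 1e-3, rel=0.01)

    def test_ground_current_balances_source(self, square_solution):
        assert square_solution.ground_current_A == pytest.approx(2e-3, rel=0.005)

    def test_linearity_in_source_current(self):
        mesh = build_mesh(square_spec())
        s1 = solve_stationary(make_problem(mesh, {}, 2e-3))
        s2 = solve_stationary(make_problem(mesh, {}, 4e-3))
        scale = np.max(np.abs(s1.V))
        assert np.max(np.abs(s2.V - 2.0 * s1.V)) < 1e-9 * scale

    def test_no_source_rejected(self):
        spec = square_spec()
        spec.source_arcs = []
        mesh = build_mesh(spec)
        with pytest.raises(FemError, match="source"):
            make_problem(mesh, {}, 2e-3)


class TestContactImpedance:
    MEMBRANE = InterfaceSpec(
        "membrane", np.array([[0.0, 0.5], [1.0, 0.5]]), 1e-3
    )

    def test_two_layer_slab_matches_series_resistance(self):
        rs = 1e-3  # Ohm m^2
        mesh = build_mesh(square_spec(interfaces=[self.MEMBRANE]))
        sol = solve_stationary(make_problem(mesh, {"membrane": rs}, 2e-3))
        Jn = 2.0  # A/m^2 at unit depth
        v_lo = sol.potential_at([0.5, 0.48])
        v_hi = sol.potential_at([0.5, 0.52])
        jump = (v_hi - v_lo) - Jn * 0.04e-3  # subtract the ohmic 0.04 mm
        assert jump == pytest.approx(rs * Jn, rel=0.01)

    def test_vanishing_impedance_recovers_continuous_solution(self):
        mesh = build_mesh(square_spec(interfaces=[self.MEMBRANE]))
        v_cont = 2.0 * 0.999e-3
        tops = []
        for rs in (1e-3, 1e-4, 1e-5, 1e-6):
            sol = solve_stationary(make_problem(mesh, {"membrane": rs}, 2e-3))
            tops.append(sol.potential_at([0.5, 0.999]))
        errs = [abs(t - v_cont) for t in tops]
        assert errs == sorted(errs, reverse=True)  # monotone convergence
        assert errs[-1] < 1e-2 * v_cont

    def test_current_conserved_across_membrane(self):
        mesh = build_mesh(square_spec(interfaces=[self.MEMBRANE]))
        sol = solve_stationary(make_problem(mesh, {"membrane": 1e-3}, 2e-3))
        assert sol.ground_current_A == pytest.approx(2e-3, rel=0.005)

    def test_nonpositive_surface_resistance_rejected(self):
        mesh = build_mesh(square_spec(interfaces=[self.MEMBRANE]))
        with pytest.raises(FemError):
            solve_stationary(make_problem(mesh, {"membrane": 0.0}, 2e-3))


class TestFibreProfiles:
    def test_constant_field_gives_flat_profile(self, square_solution):
        # horizontal path at fixed height: V = 2*y is constant along it
        path = np.array([[0.2, 0.4], [0.8, 0.4]])
        prof = fibre_potential_profile(square_solution, path, 50)
        assert np.ptp(prof.potential_V) < 1e-4 * np.max(np.abs(prof.potential_V)) + 1e-12

    def test_linear_field_gives_linear_profile(self, square_solution):
        path = np.array([[0.5, 0.05], [0.5, 0.95]])
        prof = fibre_potential_profile(square_solution, path, 60)
        coef = np.polyfit(prof.arc_mm, prof.potential_V, 1)
        resid = prof.potential_V - np.polyval(coef, prof.arc_mm)
        assert np.max(np.abs(resid)) < 0.01 * np.ptp(prof.potential_V)

    def test_mesh_refinement_changes_profile_below_one_percent(self):
        path = np.array([[0.5, 0.05], [0.5, 0.95]])
        profs = []
        for h in (0.1, 0.05):
            mesh = build_mesh(square_spec(h=h))
            sol = solve_stationary(make_problem(mesh, {}, 2e-3))
            profs.append(fibre_potential_profile(sol, path, 60).potential_V)
        rel = np.max(np.abs(profs[1] - profs[0])) / np.max(np.abs(profs[1]))
        assert rel < 0.01

    def test_path_outside_domain_rejected(self, square_solution):
        with pytest.raises(FemError):
            fibre_potential_profile(
                square_solution, np.array([[0.5, 0.5], [2.5, 0.5]]), 10
            )


@pytest.fixture(scope="module")
def domain():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_domain()


class TestSensitivityDomain:
    def test_outer_square_is_four_cochlea_widths(self, domain):
        side = domain.meta["domain_side_mm"]
        assert side == pytest.approx(4.0 * domain.meta["cochlea_width_mm"])
        outer = domain.spec.outer
        assert np.ptp(outer[:, 0]) == pytest.approx(side)
        assert np.ptp(outer[:, 1]) == pytest.approx(side)

    def test_electrode_sits_inside_basal_scala_tympani(self, domain):
        from shapely.geometry import Point, Polygon

        st = next(
            r for r in domain.spec.regions if r.name == "scala_tympani@0"
        )
        centre = domain.meta["electrode_centre"]
        assert Polygon(st.polygon).contains(Point(centre))

    def test_nerve_trunk_reaches_lower_boundary(self, domain):
        trunk = next(r for r in domain.spec.regions if r.name == "nerve_trunk")
        assert trunk.polygon[:, 1].min() == pytest.approx(
            domain.spec.outer[:, 1].min()
        )

    def test_one_fibre_per_half_turn(self, domain):
        assert len(domain.fibres) == len(domain.config.thetas)


class TestSweep:
    def test_degenerate_range_gives_zero_spread(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = sweep_parameter("Bm", value_range=(0.157, 0.157001), n_steps=2)
        assert r.max_spread_V < 1e-12

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            sweep_parameter("nonesuch", n_steps=2)

    def test_rank_parameters_orders_by_spread(self):
        def fake(name, spread):
            return SensitivityResult(
                parameter=name, values=np.array([0.0, 1.0]), profiles=[],
                max_spread_V=spread, argmax_fibre=0, argmax_station=0,
                station_arc_mm=0.0, potential_at_max=np.zeros(2),
            )

        order = rank_parameters([fake("x", 0.1), fake("y", 0.3)])
        assert order == ["y", "x"]

    def test_rank_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_parameters([])
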