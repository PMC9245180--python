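"""Unit and property tests for the continuum ICEK model."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import icekpore as ik
from icekpore.quasi1d import lateral_capacitance_fd


# ---------------------------------------------------------------------------
# Debye length
# ---------------------------------------------------------------------------

class TestDebyeLength:
    def test_model_fluid_is_about_two_angstrom(self, model_electrolyte):
        assert ik.debye_length(model_electrolyte) == pytest.approx(2.0, abs=0.1)

    def test_physiological_value(self):
        el = ik.ElectrolyteSpec(c0=0.15, valence=1, epsilon_L=78.4, T=298.0)
        # frozen from an independent SI-unit evaluation (test_units)
        assert ik.debye_length(el) == pytest.approx(7.8476, rel=1e-4)

    def test_inverse_sqrt_concentration_scaling(self, model_electrolyte):
        quarter = ik.ElectrolyteSpec(
            c0=model_electrolyte.c0 / 4.0,
            valence=model_electrolyte.valence,
            epsilon_L=model_electrolyte.epsilon_L,
            eta=model_electrolyte.eta,
            mu=model_electrolyte.mu,
            T=model_electrolyte.T,
        )
        assert ik.debye_length(quarter) == pytest.approx(
            2.0 * ik.debye_length(model_electrolyte), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [{"c0": -1.0}, {"epsilon_L": 0.0}, {"T": -5.0}])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(c0=1.0, valence=1, epsilon_L=78.0, T=298.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            ik.ElectrolyteSpec(**kwargs)

    def test_non_integer_valence_rejected(self):
        with pytest.raises(ValueError):
            ik.ElectrolyteSpec(c0=1.0, valence=0)


# ---------------------------------------------------------------------------
# lateral capacitance
# ---------------------------------------------------------------------------

class TestLateralCapacitance:
    def test_vanishes_without_cavity_depth(self):
        geom = ik.PoreGeometry(R=10, L=30, s=9, w=12, h=30.0)
        assert geom.d == 0.0
        assert ik.lateral_capacitance(geom) == 0.0

    def test_decreases_with_wall_thickness(self):
        thin = ik.PoreGeometry(R=10, L=30, s=9.0, w=12, h=10)
        thick = ik.PoreGeometry(R=10, L=30, s=18.0, w=12, h=10)
        assert ik.lateral_capacitance(thin) > ik.lateral_capacitance(thick)

    def test_increases_with_depth_and_with_length_at_fixed_h(self):
        c_of_d = [
            ik.lateral_capacitance(ik.PoreGeometry(R=10, L=30, s=9, w=12, h=h))
            for h in (25.0, 20.0, 10.0, 0.0)
        ]
        assert all(a < b for a, b in zip(c_of_d, c_of_d[1:]))
        c_of_l = [
            ik.lateral_capacitance(ik.PoreGeometry(R=10, L=L, s=9, w=12, h=10.0))
            for L in (15.0, 30.0, 60.0, 90.0)
        ]
        assert all(a < b for a, b in zip(c_of_l, c_of_l[1:]))

    def test_matches_finite_difference_reference(self, base_geometry):
        closed = ik.lateral_capacitance(base_geometry)
        fd = lateral_capacitance_fd(base_geometry)
        assert closed == pytest.approx(fd, rel=0.02)

    @pytest.mark.parametrize("L", [18.0, 30.0, 60.0])
    @pytest.mark.parametrize("s", [6.0, 9.0, 18.0])
    @pytest.mark.parametrize("d", [5.0, 10.0, 15.0])
    def test_quasi1d_oracle_grid(self, L, s, d):
        """Closed form vs the discretised cavity–lumen potential solve, on a
        3x3x3 (L, s, d) grid, within 2%."""
        geom = ik.PoreGeometry(R=10.0, L=L, s=s, w=12.0, h=L - d, epsilon_S=2.0)
        assert ik.lateral_capacitance(geom) == pytest.approx(
            lateral_capacitance_fd(geom), rel=0.02
        )

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ik.PoreGeometry(R=10, L=30, s=9, w=12, h=31.0)  # d < 0
        with pytest.raises(ValueError):
            ik.PoreGeometry(R=-1, L=30, s=9, w=12, h=10)


# ---------------------------------------------------------------------------
# induced charge, density, selectivity
# ---------------------------------------------------------------------------

class TestInducedCharge:
    def test_zero_at_zero_voltage(self, base_geometry):
        assert ik.induced_charge(base_geometry, ik.DriveCondition(0.0)) == 0.0

    def test_antisymmetric_in_voltage(self, base_geometry):
        plus = ik.induced_charge(base_geometry, ik.DriveCondition(0.75))
        minus = ik.induced_charge(base_geometry, ik.DriveCondition(-0.75))
        assert plus == -minus

    def test_sign_opposes_voltage_for_default_orientation(self, base_geometry):
        assert ik.induced_charge(base_geometry, ik.DriveCondition(0.75)) < 0

    def test_value_against_fd_capacitance(self, base_geometry):
        q = ik.induced_charge(base_geometry, ik.DriveCondition(0.75))
        assert q == pytest.approx(-lateral_capacitance_fd(base_geometry) * 0.75,
                                  rel=0.02)

    def test_cavity_side_flips_sign(self, base_geometry):
        mirrored = ik.PoreGeometry(
            R=10, L=30, s=9, w=12, h=10,
            cavity_side=ik.CavitySide.FACING_GROUNDED_RESERVOIR,
        )
        drive = ik.DriveCondition(0.75)
        assert ik.induced_charge(mirrored, drive) == -ik.induced_charge(
            base_geometry, drive
        )

    def test_mean_density_identity(self, base_geometry):
        drive = ik.DriveCondition(0.75)
        rho = ik.mean_charge_density(base_geometry, drive)
        q = ik.induced_charge(base_geometry, drive)
        vol = math.pi * base_geometry.R**2 * base_geometry.L
        assert rho * vol == pytest.approx(q, rel=1e-12)

    def test_density_quarter_on_radius_doubling(self, base_geometry):
        wide = ik.PoreGeometry(R=20, L=30, s=9, w=12, h=10)
        drive = ik.DriveCondition(0.75)
        ratio = (
            ik.induced_charge(base_geometry, drive) / (math.pi * 10**2)
        ) / (ik.induced_charge(wide, drive) / (math.pi * 20**2))
        # same q_N would give exactly 4; here q_N itself changes with R via
        # the log term, so check the explicit normalisation instead
        vol_density = ik.mean_charge_density(base_geometry, drive)
        assert vol_density == pytest.approx(
            ik.induced_charge(base_geometry, drive) / (math.pi * 100.0 * 30.0),
            rel=1e-12,
        )
        assert ratio > 0


class TestSelectivity:
    def test_zero_at_zero_voltage(self, base_geometry, model_electrolyte):
        assert ik.selectivity(base_geometry, model_electrolyte,
                              ik.DriveCondition(0.0)) == 0.0

    def test_odd_in_voltage(self, base_geometry, model_electrolyte):
        plus = ik.selectivity(base_geometry, model_electrolyte, ik.DriveCondition(0.75))
        minus = ik.selectivity(base_geometry, model_electrolyte,
                               ik.DriveCondition(-0.75))
        assert plus == -minus

    def test_quadratic_magnitude(self, base_geometry, model_electrolyte):
        j1 = ik.selectivity(base_geometry, model_electrolyte, ik.DriveCondition(0.75))
        j2 = ik.selectivity(base_geometry, model_electrolyte, ik.DriveCondition(1.5))
        assert abs(j2) == pytest.approx(4.0 * abs(j1), rel=1e-12)

    def test_sign_follows_pore_charge(self, base_geometry, model_electrolyte):
        drive = ik.DriveCondition(0.75)
        q = ik.induced_charge(base_geometry, drive)
        j = ik.selectivity(base_geometry, model_electrolyte, drive)
        assert math.copysign(1, j) == math.copysign(1, q)


# ---------------------------------------------------------------------------
# electroosmotic flow
# ---------------------------------------------------------------------------

class TestEofFlow:
    def test_zero_at_zero_voltage(self, base_geometry, model_electrolyte):
        with pytest.warns(ik.ThinLayerWarning):
            q, v = ik.eof_flow(base_geometry, model_electrolyte, ik.DriveCondition(0.0))
        assert (q, v) == (0.0, 0.0)

    def test_even_and_negative_toward_cavity(self, base_geometry, model_electrolyte):
        with pytest.warns(ik.ThinLayerWarning):
            _, v_plus = ik.eof_flow(base_geometry, model_electrolyte,
                                    ik.DriveCondition(0.75))
            _, v_minus = ik.eof_flow(base_geometry, model_electrolyte,
                                     ik.DriveCondition(-0.75))
        assert v_plus == v_minus
        assert v_plus < 0

    def test_quadratic_voltage_scaling(self, base_geometry, model_electrolyte):
        with pytest.warns(ik.ThinLayerWarning):
            _, v1 = ik.eof_flow(base_geometry, model_electrolyte,
                                ik.DriveCondition(0.75))
            _, v2 = ik.eof_flow(base_geometry, model_electrolyte,
                                ik.DriveCondition(1.5))
        assert v2 == pytest.approx(4.0 * v1, rel=1e-12)

    def test_velocity_is_flow_over_area(self, base_geometry, model_electrolyte):
        with pytest.warns(ik.ThinLayerWarning):
            q, v = ik.eof_flow(base_geometry, model_electrolyte,
                               ik.DriveCondition(0.75))
        assert v == pytest.approx(q / (math.pi * base_geometry.R**2), rel=1e-12)

    def test_debye_overlap_is_hard_error(self, model_electrolyte):
        tiny = ik.PoreGeometry(R=1.5, L=30, s=9, w=12, h=10)
        with pytest.raises(ik.DebyeOverlapError):
            ik.eof_flow(tiny, model_electrolyte, ik.DriveCondition(0.75))

    def test_no_warning_for_thin_layers(self, kcl_1m):
        import warnings

        big = ik.PoreGeometry(R=100, L=300, s=50, w=100, h=100, epsilon_S=7.5)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ik.eof_flow(big, kcl_1m, ik.DriveCondition(1.0))


# ---------------------------------------------------------------------------
# fixed surface charge and threshold voltage
# ---------------------------------------------------------------------------

class TestFixedCharge:
    def test_zero_charge_zero_velocity(self, base_geometry, kcl_1m):
        v = ik.fixed_charge_velocity(base_geometry, kcl_1m, ik.DriveCondition(1.0),
                                     ik.SurfaceChargeSpec(0.0))
        assert v == 0.0

    def test_bilinear(self, base_geometry, kcl_1m):
        drive = ik.DriveCondition(1.0)
        v1 = ik.fixed_charge_velocity(base_geometry, kcl_1m, drive,
                                      ik.SurfaceChargeSpec(2.5))
        v2 = ik.fixed_charge_velocity(base_geometry, kcl_1m, drive,
                                      ik.SurfaceChargeSpec(5.0))
        v3 = ik.fixed_charge_velocity(base_geometry, kcl_1m, ik.DriveCondition(-1.0),
                                      ik.SurfaceChargeSpec(2.5))
        assert v2 == pytest.approx(2.0 * v1, rel=1e-12)
        assert v3 == -v1

    def test_ph_model_interface(self):
        spec = ik.SurfaceChargeSpec.from_ph_model(lambda ph: 3.0 * (ph - 4.1), 6.1)
        assert spec.sigma_w == pytest.approx(6.0)


class TestThresholdVoltage:
    def test_zero_for_neutral_wall(self, base_geometry, kcl_1m):
        assert ik.threshold_voltage(base_geometry, kcl_1m,
                                    ik.SurfaceChargeSpec(0.0)) == 0.0

    def test_self_consistency(self, kcl_1m):
        """At ΔV*, fixed-charge and induced-charge EO speeds agree to round-off."""
        geom = ik.PoreGeometry(R=100, L=300, s=50, w=100, h=100, epsilon_S=7.5)
        charge = ik.SurfaceChargeSpec(5.0)
        dv = ik.threshold_voltage(geom, kcl_1m, charge)
        drive = ik.DriveCondition(dv)
        _, v_ic = ik.eof_flow(geom, kcl_1m, drive)
        v_fc = ik.fixed_charge_velocity(geom, kcl_1m, drive, charge)
        assert abs(abs(v_ic) - abs(v_fc)) / abs(v_fc) < 1e-9

    def test_monotone_in_surface_charge(self, kcl_1m):
        geom = ik.PoreGeometry(R=100, L=300, s=50, w=100, h=100, epsilon_S=7.5)
        dvs = [ik.threshold_voltage(geom, kcl_1m, ik.SurfaceChargeSpec(sig))
               for sig in (1.0, 2.5, 5.0, 10.0)]
        assert all(a < b for a, b in zip(dvs, dvs[1:]))

    def test_infinite_without_cavity(self, kcl_1m):
        geom = ik.PoreGeometry(R=100, L=300, s=50, w=100, h=300.0, epsilon_S=7.5)
        assert ik.threshold_voltage(geom, kcl_1m, ik.SurfaceChargeSpec(5.0)) == math.inf


# ---------------------------------------------------------------------------
# far field
# ---------------------------------------------------------------------------

class TestFarField:
    def test_micron_distance_value(self):
        # 0.1 m/s at a 20 nm pore mouth -> 0.4e-4 m/s at 1 um
        assert ik.far_field_velocity(0.1, 20e-9, 1e-6) == pytest.approx(
            0.4e-4, rel=1e-12
        )

    def test_identity_at_pore_mouth(self):
        assert ik.far_field_velocity(-3.3, 10.0, 10.0) == -3.3

    def test_inverse_square(self):
        assert ik.far_field_velocity(1.0, 10.0, 40.0) == pytest.approx(
            ik.far_field_velocity(1.0, 10.0, 20.0) / 4.0, rel=1e-12
        )

    def test_inside_pore_rejected(self):
        with pytest.raises(ValueError):
            ik.far_field_velocity(1.0, 10.0, 5.0)


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------

class TestSweep:
    @pytest.fixture(autouse=True)
    def _quiet(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ik.ThinLayerWarning)
            yield

    def test_single_point_matches_direct_calls(self, base_geometry, model_electrolyte):
        table = ik.sweep(base_geometry, model_electrolyte, [0.75])
        assert len(table) == 1
        pred = ik.predict(base_geometry, model_electrolyte, ik.DriveCondition(0.75))
        assert table.loc[0, "v_eo"] == pred.v_eo
        assert table.loc[0, "q_N"] == pred.q_N
        assert table.loc[0, "C_s"] == pred.C_s

    def test_length_sweep_has_interior_maximum(self, model_electrolyte):
        """|v_eo|(L) at fixed residual solid h: rises then falls (competition
        between E_z = ΔV/L and the growing lateral capacitance)."""
        lengths = np.arange(18.0, 91.0, 3.0)
        geoms = [ik.PoreGeometry(R=10, L=L, s=9, w=12, h=10.0) for L in lengths]
        table = ik.sweep(geoms, model_electrolyte, [0.75])
        v = np.abs(table["v_eo"].to_numpy())
        k = int(np.argmax(v))
        assert 0 < k < len(v) - 1
        assert v[0] < v[k] and v[-1] < v[k]

    def test_depth_sweep_monotone_from_zero(self, model_electrolyte):
        depths = np.arange(0.0, 25.0, 2.5)
        geoms = [ik.PoreGeometry(R=10, L=30, s=9, w=12, h=30.0 - d) for d in depths]
        table = ik.sweep(geoms, model_electrolyte, [0.75])
        v = np.abs(table["v_eo"].to_numpy())
        assert v[0] == 0.0
        assert all(a < b for a, b in zip(v, v[1:]))

    def test_empty_grid_rejected(self, base_geometry, model_electrolyte):
        with pytest.raises(ValueError):
            ik.sweep(base_geometry, model_electrolyte, [])
        with pytest.raises(ValueError):
            ik.sweep([], model_electrolyte, [0.75])


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

geometries = st.builds(
    ik.PoreGeometry,
    R=st.floats(5.0, 200.0),
    L=st.floats(10.0, 500.0),
    s=st.floats(2.0, 50.0),
    w=st.floats(2.0, 50.0),
    h=st.floats(0.0, 1.0),  # fraction of L, rescaled below
    epsilon_S=st.floats(1.0, 20.0),
).map(
    lambda g: ik.PoreGeometry(
        R=g.R, L=g.L, s=g.s, w=g.w, h=g.h * g.L, epsilon_S=g.epsilon_S
    )
)
voltages = st.floats(-5.0, 5.0, allow_subnormal=False)


@given(geom=geometries, dv=voltages)
def test_charge_and_selectivity_antisymmetry(geom, dv):
    el = ik.ElectrolyteSpec(c0=2.0, valence=1, epsilon_L=83.2, eta=0.35, T=250.0)
    assert ik.induced_charge(geom, ik.DriveCondition(-dv)) == -ik.induced_charge(
        geom, ik.DriveCondition(dv)
    )
    assert ik.selectivity(geom, el, ik.DriveCondition(-dv)) == -ik.selectivity(
        geom, el, ik.DriveCondition(dv)
    )


@given(geom=geometries, dv=voltages, k=st.sampled_from([2.0, 3.0, 0.5]))
def test_quadratic_voltage_law(geom, dv, k):
    el = ik.ElectrolyteSpec(c0=2.0, valence=1, epsilon_L=83.2, eta=0.35, T=250.0)
    j1 = ik.selectivity(geom, el, ik.DriveCondition(dv))
    j2 = ik.selectivity(geom, el, ik.DriveCondition(k * dv))
    assert abs(j2) == pytest.approx(k**2 * abs(j1), rel=1e-9, abs=1e-30)


@given(geom=geometries, dv=st.floats(0.01, 5.0))
def test_eof_unidirectional(geom, dv):
    import warnings

    el = ik.ElectrolyteSpec(c0=2.0, valence=1, epsilon_L=83.2, eta=0.35, T=250.0)
    if ik.debye_length(el) >= geom.R:
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ik.ThinLayerWarning)
        _, v_plus = ik.eof_flow(geom, el, ik.DriveCondition(dv))
        _, v_minus = ik.eof_flow(geom, el, ik.DriveCondition(-dv))
    assert v_plus == v_minus
    assert v_plus <= 0  # toward the cavity opening (biased side by default)


@given(geom=geometries)
def test_degenerate_cavity_limit(geom):
    """d -> 0 kills capacitance, induced charge, selectivity and EOF."""
    flat = ik.PoreGeometry(R=geom.R, L=geom.L, s=geom.s, w=geom.w, h=geom.L,
                           epsilon_S=geom.epsilon_S)
    el = ik.ElectrolyteSpec(c0=2.0, valence=1, epsilon_L=83.2, eta=0.35, T=250.0)
    assert ik.lateral_capacitance(flat) == 0.0
    assert ik.induced_charge(flat, ik.DriveCondition(1.0)) == 0.0
    assert ik.selectivity(flat, el, ik.DriveCondition(1.0)) == 0.0
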