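"""Machine database, energy grid, beam optics, and MU calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oofdose.fixtures import make_machine_database
from oofdose.machine import (
    EnergyLayerRecord,
    MachineDatabase,
    SpotSpec,
    back_project_spot,
    build_energy_grid,
    calibrate_protons_per_mu,
    forward_project,
    lateral_spot_sigma,
    load_machine_database,
    reference_field_positions,
    save_machine_database,
)


class TestEnergyGrid:
    def test_commissioning_grid_has_27_entries(self):
        grid = build_energy_grid(100.0, 226.7, 5.0)
        assert len(grid) == 27
        assert grid[0] == 100.0
        assert grid[-1] == 226.7
        assert grid[-2] == 225.0

    def test_degenerate_range(self):
        assert build_energy_grid(100.0, 100.0, 5.0) == [100.0]

    def test_exact_multiple(self):
        assert build_energy_grid(100.0, 110.0, 5.0) == [100.0, 105.0, 110.0]

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            build_energy_grid(100.0, 200.0, 0.0)

    @given(
        e_min=st.floats(50, 200),
        span=st.floats(0, 100),
        step=st.floats(0.5, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_grid_ascending_and_capped(self, e_min, span, step):
        grid = build_energy_grid(e_min, e_min + span, step)
        assert np.all(np.diff(grid) > 0) or len(grid) == 1
        assert grid[-1] == pytest.approx(e_min + span)


def record(a0=1e-5, a1=0.0, a2=0.25, e=150.0):
    return EnergyLayerRecord(e, 0.9, (a0, a1, a2), (a0, a1, a2), 1e8)


class TestLateralSigma:
    def test_pure_beam_size_no_divergence(self):
        r = record(a0=0.0, a1=0.0, a2=0.25)
        for z in (0.0, 10.0, 50.0):
            assert float(lateral_spot_sigma(r, z)) == pytest.approx(0.5)

    def test_closed_form_drift(self):
        r = record(a0=1e-4, a1=0.0, a2=0.25)
        assert float(lateral_spot_sigma(r, 50.0)) == pytest.approx(
            np.sqrt(0.5), abs=1e-9
        )

    def test_matches_ray_sampling_oracle(self, rng):
        """sigma^2(z) equals the variance of a million sampled rays."""
        a0, a1, a2 = 4e-5, -5e-4, 0.36
        r = record(a0=a0, a1=a1, a2=a2)
        cov = np.array([[a2, a1], [a1, a0]])
        samp = rng.multivariate_normal([0, 0], cov, size=1_000_000)
        for z in (10.0, 30.0, 60.0):
            x_at_z = samp[:, 0] + samp[:, 1] * z
            assert x_at_z.var() == pytest.approx(
                float(lateral_spot_sigma(r, z)) ** 2, rel=0.01
            )

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            record(a0=1e-6, a1=1.0, a2=0.25)


class TestBackProjection:
    def test_axial_spot(self):
        nz = back_project_spot(SpotSpec((0.0, 0.0), 1.0))
        assert nz.exit_position == (0.0, 0.0)
        assert nz.direction[2] == pytest.approx(1.0)

    def test_similar_triangles(self):
        """x-focus 200 cm, exit plane 50 cm: x_exit = 2 (200-50)/200."""
        nz = back_project_spot(
            SpotSpec((2.0, 0.0), 1.0), foci=(200.0, 180.0), exit_plane_z=50.0
        )
        assert nz.exit_position[0] == pytest.approx(1.5)

    def test_forward_projection_round_trip(self):
        spot = SpotSpec((2.3, -1.7), 1.0)
        nz = back_project_spot(spot)
        xy = forward_project(nz)
        assert xy[0] == pytest.approx(2.3, abs=1e-9)
        assert xy[1] == pytest.approx(-1.7, abs=1e-9)

    def test_focus_inside_nozzle_rejected(self):
        with pytest.raises(ValueError):
            back_project_spot(SpotSpec((1.0, 0.0), 1.0), foci=(40.0, 180.0))


class TestMuCalibration:
    def test_arithmetic(self):
        assert calibrate_protons_per_mu(1e-9, 1e-3) == pytest.approx(1e6)

    def test_inverse_proportionality(self):
        assert calibrate_protons_per_mu(2e-9, 1e-3) == pytest.approx(
            calibrate_protons_per_mu(1e-9, 1e-3) / 2
        )

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibrate_protons_per_mu(0.0, 1e-3)

    def test_reference_field_layout(self):
        """1681 spots at 0.25 cm spacing in a symmetric square."""
        pos = reference_field_positions()
        assert pos.shape == (1681, 2)
        np.testing.assert_allclose(pos.mean(axis=0), [0, 0], atol=1e-12)
        xs = np.unique(pos[:, 0])
        assert np.allclose(np.diff(xs), 0.25)


class TestDatabase:
    def test_interpolation_exact_at_nodes(self, machine_db):
        for r in machine_db.records[::5]:
            got = machine_db.interpolate(r.mean_energy)
            assert got.energy_spread == r.energy_spread
            assert got.protons_per_mu == r.protons_per_mu

    def test_interpolation_monotone_between_nodes(self, machine_db):
        e = np.linspace(100.0, 226.7, 301)
        ppm = [machine_db.interpolate(x).protons_per_mu for x in e]
        assert np.all(np.diff(ppm) > 0)  # protons/MU increase with energy

    def test_linear_between_adjacent_nodes(self, machine_db):
        lo = machine_db.records[3]
        hi = machine_db.records[4]
        mid = machine_db.interpolate(
            0.5 * (lo.mean_energy + hi.mean_energy)
        )
        assert mid.energy_spread == pytest.approx(
            0.5 * (lo.energy_spread + hi.energy_spread)
        )

    def test_out_of_span_rejected(self, machine_db):
        with pytest.raises(ValueError):
            machine_db.interpolate(99.0)

    def test_file_round_trip(self, machine_db, tmp_path):
        path = tmp_path / "machine.tsv"
        save_machine_database(machine_db, path)
        back = load_machine_database(path)
        assert back.foci == machine_db.foci
        assert len(back.records) == len(machine_db.records)
        for a, b in zip(back.records, machine_db.records):
            assert a.mean_energy == pytest.approx(b.mean_energy, rel=1e-9)
            assert a.fe_moments_x == pytest.approx(b.fe_moments_x, rel=1e-8)

    def test_unsorted_records_rejected(self):
        recs = [record(e=150.0), record(e=120.0)]
        with pytest.raises(ValueError, match="increasing"):
            MachineDatabase(recs)
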