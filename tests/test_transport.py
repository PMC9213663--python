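"""Surrogate transport engine: scoring, oracles, and invariants."""

import numpy as np
import pytest

from oofdose import fixtures as fx
from oofdose.bragg import bragg_curve, extract_r80
from oofdose.conversion import ConversionTables, log_energy_bins
from oofdose.gamma import GammaCriteria, gamma_index
from oofdose.stopping import WATER, csda_range, energy_from_range
from oofdose.transport import (
    TransportConfig,
    X0_WATER,
    _pv,
    estimate_statistical_uncertainty,
    run_transport,
    score_neutron_dose_equivalent,
)

MEV_TO_J = 1.602176634e-13


def depth_dose(maps, phantom):
    """Integral depth dose along the beam (-y), sorted by depth."""
    y = phantom.voxel_centers(1)
    depth = 3.0 - y
    order = np.argsort(depth)
    return depth[order], maps.dose_primary_proton.sum(axis=(0, 2))[order]


class TestSingleSpot:
    def test_scored_r80_matches_analytical_model(self, watertank_run,
                                                 machine_db):
        """Scored depth dose reproduces the analytical R80 within 0.05 cm."""
        depth, dd = depth_dose(watertank_run["maps"],
                               watertank_run["phantom"])
        spread = machine_db.interpolate(150.0).energy_spread
        zz = np.linspace(0.1, 20.0, 8000)
        analytic = extract_r80(zz, bragg_curve(zz, 150.0, spread))
        assert extract_r80(depth, dd) == pytest.approx(analytic, abs=0.05)

    def test_energy_conservation_bound(self, watertank_run):
        """Total deposited energy cannot exceed the delivered beam energy."""
        m = watertank_run["maps"]
        v = m.spacing**3
        conv = MEV_TO_J / (v * 1e-3)
        deposited = (
            m.dose_primary_proton.sum()
            + m.dose_secondary_proton.sum()
            + m.dose_gamma.sum()
        ) / conv * m.histories
        # beam energy incl. air-path correction and straggling margin
        assert deposited <= m.histories * 155.0

    def test_components_non_negative(self, watertank_run):
        m = watertank_run["maps"]
        for g in (m.dose_primary_proton, m.dose_secondary_proton,
                  m.dose_gamma, m.neutron_H, m.neutron_fluence):
            assert np.all(g >= 0)

    def test_secondary_is_total_minus_primary(self, watertank_run):
        """The all-proton tally minus the primary tally is the secondary."""
        m = watertank_run["maps"]
        total = m.dose_primary_proton + m.dose_secondary_proton
        np.testing.assert_allclose(
            total - m.dose_primary_proton, m.dose_secondary_proton,
            rtol=1e-9, atol=1e-25,
        )

    def test_neutron_h_consistent_with_spectrum_folding(self, watertank_run):
        """Folding the scored spectrum with h(E) reproduces neutron_H to
        within the room-return and sub-thermal-bin differences."""
        m = watertank_run["maps"]
        h_from_spec = score_neutron_dose_equivalent(
            m.neutron_fluence, ConversionTables(), m.energy_bin_edges
        )
        assert h_from_spec.sum() == pytest.approx(m.neutron_H.sum(), rel=0.05)

    def test_maps_h5_round_trip(self, watertank_run, tmp_path):
        m = watertank_run["maps"]
        path = tmp_path / "maps.h5"
        m.save(path)
        back = type(m).load(path)
        np.testing.assert_array_equal(back.dose_primary_proton,
                                      m.dose_primary_proton)
        np.testing.assert_array_equal(back.neutron_H, m.neutron_H)
        assert back.histories == m.histories


class TestInFieldOracle:
    @pytest.fixture(scope="class")
    def oracle_setup(self, machine_db):
        spacing = 0.25
        phantom = fx.make_water_tank(spacing=spacing, shape=(48, 88, 48))
        plan = fx.make_single_spot_plan(150.0)
        maps = run_transport(
            plan, machine_db, phantom,
            TransportConfig(histories=120_000, seed=3),
        )
        return phantom, maps, machine_db.interpolate(150.0)

    def test_global_gamma_3pct_3mm_vs_pencil_beam_convolution(
        self, oracle_setup
    ):
        """Engine in-field dose vs an independent pencil-beam convolution:
        analytical depth dose times a Gaussian whose variance combines the
        vacuum phase-space envelope with the Fermi-Eyges scattering
        integral, evaluated by direct numerical integration."""
        phantom, maps, rec = oracle_setup
        spacing = phantom.spacing
        x = phantom.voxel_centers(0)
        y = phantom.voxel_centers(1)
        z = phantom.voxel_centers(2)
        depth = 3.0 - y
        r0 = float(csda_range(WATER, 150.0))
        ds = 0.02
        s = np.arange(0.0, r0 + 1.0, ds)
        e_s = energy_from_range(WATER, np.maximum(r0 - s, 1e-4))
        t_scatter = (14.1 / _pv(np.maximum(e_s, 5.0))) ** 2 / X0_WATER
        var_ms = np.array([
            np.sum((d - s[s < d]) ** 2 * t_scatter[s < d]) * ds if d > 0
            else 0.0
            for d in depth
        ])
        t_noz = 47.0 + depth
        a0x, a1x, a2x = rec.fe_moments_x
        a0y, a1y, a2y = rec.fe_moments_y
        varx = a2x + 2 * a1x * t_noz + a0x * t_noz**2 + var_ms
        varz = a2y + 2 * a1y * t_noz + a0y * t_noz**2 + var_ms
        dd = bragg_curve(np.maximum(depth, 1e-3), 150.0, rec.energy_spread,
                         gamma_frac=0.0)
        dd[depth <= 0] = 0.0
        gx = (np.exp(-x[:, None] ** 2 / (2 * varx[None, :]))
              / np.sqrt(2 * np.pi * varx[None, :]))
        gz = (np.exp(-z[:, None] ** 2 / (2 * varz[None, :]))
              / np.sqrt(2 * np.pi * varz[None, :]))
        oracle = (gx[:, :, None] * dd[None, :, None]
                  * np.transpose(gz)[None, :, :]) * 1.602176634e-10
        crit = GammaCriteria(3.0, 3.0, low_dose_threshold_percent=10.0)
        _, rate = gamma_index(oracle, maps.dose_primary_proton, crit, spacing)
        assert rate >= 95.0


class TestErrors:
    def test_energy_outside_machine_span(self, machine_db):
        phantom = fx.make_water_tank(spacing=0.5, shape=(10, 20, 10))
        plan = fx.make_single_spot_plan(95.0)
        with pytest.raises(ValueError, match="span"):
            run_transport(plan, machine_db, phantom,
                          TransportConfig(histories=10, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TransportConfig(histories=0)
        with pytest.raises(ValueError):
            TransportConfig(world_medium="mud")
        with pytest.raises(ValueError):
            TransportConfig(room_return_albedo=1.5)
        with pytest.raises(ValueError):
            TransportConfig(batches=1)


class TestNeutronScoring:
    def setup_method(self):
        self.tables = ConversionTables()
        self.edges = log_energy_bins()
        self.centers = np.sqrt(self.edges[:-1] * self.edges[1:])

    def test_single_node_spectrum(self):
        """Monoenergetic unit fluence returns h at that energy."""
        phi = np.zeros(self.centers.size)
        j = np.argmin(np.abs(self.centers - 1.0))
        phi[j] = 1.0
        h = score_neutron_dose_equivalent(phi, self.tables, self.edges)
        assert h == pytest.approx(float(self.tables.h_of(self.centers[j])))

    def test_linearity_over_bins(self):
        phi1 = np.zeros(self.centers.size)
        phi2 = np.zeros(self.centers.size)
        phi1[60] = 2.0
        phi2[80] = 3.0
        h12 = score_neutron_dose_equivalent(phi1 + phi2, self.tables,
                                            self.edges)
        h1 = score_neutron_dose_equivalent(phi1, self.tables, self.edges)
        h2 = score_neutron_dose_equivalent(phi2, self.tables, self.edges)
        assert h12 == pytest.approx(h1 + h2, rel=1e-12)

    def test_broad_spectrum_matches_fine_grid_trapezoid(self):
        """Bin-sum folding agrees with trapezoid integration on a 10x
        finer energy grid within 1%."""
        # smooth lognormal-ish spectral density around 1 MeV
        def density(e):
            return np.exp(-0.5 * (np.log(e / 1.0) / 1.2) ** 2) / e

        phi_bins = density(self.centers) * np.diff(self.edges)
        h_binned = score_neutron_dose_equivalent(
            phi_bins, self.tables, self.edges
        )
        fine = np.geomspace(self.edges[0], self.edges[-1],
                            10 * self.centers.size)
        integrand = density(fine) * np.array(
            [float(self.tables.h_of(min(max(e, 2.5e-8), 1000.0)))
             for e in fine]
        )
        h_fine = np.trapezoid(integrand, fine)
        assert h_binned == pytest.approx(h_fine, rel=0.01)

    def test_spectrum_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_neutron_dose_equivalent(
                np.zeros(5), self.tables, self.edges
            )


class TestBatchUncertainty:
    def test_identical_batches_zero_uncertainty(self):
        b = np.ones((10, 4, 4))
        assert np.all(estimate_statistical_uncertainty(b) == 0)

    def test_fewer_than_two_batches_rejected(self):
        with pytest.raises(ValueError):
            estimate_statistical_uncertainty(np.ones((1, 4)))

    def test_matches_sigma_over_sqrt_n_for_normal_batches(self, rng):
        """Estimator recovers sigma/sqrt(n)/mu within 20% over repeats."""
        n, mu, sigma = 10, 5.0, 0.5
        estimates = []
        for _ in range(100):
            b = rng.normal(mu, sigma, size=(n, 1))
            estimates.append(estimate_statistical_uncertainty(b)[0])
        expected = sigma / np.sqrt(n) / mu
        assert np.mean(estimates) == pytest.approx(expected, rel=0.2)

    def test_scaling_with_batch_count(self, rng):
        """Uncertainty falls like 1/sqrt(batches) within 30%."""
        sig = []
        for n in (10, 40):
            vals = [
                estimate_statistical_uncertainty(
                    rng.normal(5.0, 0.5, size=(n, 1))
                )[0]
                for _ in range(200)
            ]
            sig.append(np.mean(vals))
        assert sig[0] / sig[1] == pytest.approx(2.0, rel=0.3)
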