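"""Dose-equivalent composition, organ doses, risk scaling, profiles."""

import numpy as np
import pytest

from oofdose.conversion import LAR_TABLE
from oofdose.reporting import (
    DoseCompositionRule,
    compose_total_dose_equivalent,
    compute_organ_doses,
    estimate_lar_risk,
    physical_target_dose,
    profile_vs_distance,
    round_sig,
)
from oofdose.transport import ComponentDoseMaps


def maps_from(dp, ds, dg, hn):
    shape = dp.shape
    z = np.zeros(shape)
    return ComponentDoseMaps(
        spacing=0.2, origin=np.zeros(3),
        dose_primary_proton=dp, dose_secondary_proton=ds, dose_gamma=dg,
        neutron_H=hn, neutron_H_thermal=z.copy(),
        neutron_fluence=np.zeros((1, *shape)),
        energy_bin_edges=np.array([1e-9, 1e3]),
        rel_uncertainty={}, histories=1,
    )


class TestPhysicalTargetDose:
    def test_course_prescription(self):
        """50.4 Gy(RBE) at RBE 1.1 is 45.8 Gy physical."""
        assert physical_target_dose(50.4, 1.1) == 45.8

    def test_identity_at_unit_dose(self):
        assert physical_target_dose(1.1, 1.1) == 1.0

    def test_tld_irradiation_plan(self):
        assert physical_target_dose(100.8, 1.1) == 91.6

    def test_zero_rbe_rejected(self):
        with pytest.raises(ValueError):
            physical_target_dose(50.4, 0.0)


class TestComposition:
    def test_stated_rule_arithmetic(self):
        """(1 uGy, 1 uGy, 10 uSv) composes to 12.1 uSv."""
        one = np.ones((2, 2, 2))
        m = maps_from(one * 1.0, one * 99.0, one * 1.0, one * 10.0)
        h = compose_total_dose_equivalent(m)
        assert np.allclose(h, 12.1)

    def test_all_zero(self):
        z = np.zeros((2, 2, 2))
        m = maps_from(z, z, z, z)
        assert np.all(compose_total_dose_equivalent(m) == 0)

    def test_total_dominates_components(self):
        rng = np.random.default_rng(0)
        dp, ds, dg, hn = (rng.random((3, 3, 3)) for _ in range(4))
        m = maps_from(dp, ds, dg, hn)
        h = compose_total_dose_equivalent(m)
        assert np.all(h >= dp - 1e-12)
        assert np.all(h >= dg - 1e-12)
        assert np.all(h >= hn - 1e-12)

    def test_grid_mismatch_rejected(self):
        m = maps_from(*(np.zeros((2, 2, 2)) for _ in range(4)))
        m.dose_gamma = np.zeros((3, 3, 3))
        with pytest.raises(ValueError):
            compose_total_dose_equivalent(m)


class TestOrganDoses:
    def test_thyroid_course_total(self):
        """2673 uSv/Gy over a 45.8 Gy course rounds to 120 mSv."""
        grid = np.full((4, 4, 4), 2673.0)
        mask = np.zeros_like(grid, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        out = compute_organ_doses(grid, {"thyroid": mask}, 45.8)
        assert out.loc[0, "total_mSv"] == 120.0

    def test_uniform_grid_mean(self):
        grid = np.full((4, 4, 4), 7.5)
        masks = {f"o{i}": np.ones_like(grid, dtype=bool) for i in range(3)}
        out = compute_organ_doses(grid, masks, 10.0)
        assert np.allclose(out.H_per_target_uSv_per_Gy, 7.5)

    def test_standard_roi_set_has_28_organs(self, brain_case):
        ph = brain_case["phantom"]
        organs = {k: v for k, v in ph.roi_masks.items()
                  if k not in ("target", "body")}
        assert len(organs) == 28
        grid = np.ones(ph.shape)
        out = compute_organ_doses(grid, organs, 45.8)
        assert len(out) == 28

    def test_linear_in_course_dose(self):
        grid = np.full((3, 3, 3), 1234.5)
        mask = np.ones_like(grid, dtype=bool)
        a = compute_organ_doses(grid, {"o": mask}, 10.0)
        b = compute_organ_doses(grid, {"o": mask}, 20.0)
        # totals are rounded to 2 s.f.; compare with matching rounding
        assert b.loc[0, "total_mSv"] == pytest.approx(
            round_sig(2 * grid[0, 0, 0] * 10.0 / 1000.0, 2)
        )
        assert a.loc[0, "total_mSv"] == pytest.approx(
            round_sig(grid[0, 0, 0] * 10.0 / 1000.0, 2)
        )

    def test_empty_mask_rejected(self):
        grid = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="empty"):
            compute_organ_doses(grid, {"o": np.zeros_like(grid, bool)}, 1.0)


class TestRisk:
    def test_breast_worked_example(self):
        """17 mSv at LAR 914 -> 0.2%."""
        assert estimate_lar_risk(17.0, LAR_TABLE["breast"]["female"]) == 0.2

    def test_thyroid_men_worked_example(self):
        """120 mSv at LAR 76 -> 0.1%."""
        assert estimate_lar_risk(120.0, LAR_TABLE["thyroid"]["male"]) == 0.1

    def test_zero_dose(self):
        assert estimate_lar_risk(0.0, 914.0) == 0.0

    def test_linearity_before_rounding(self):
        # compare unrounded expectation at a dose where rounding is inert
        assert estimate_lar_risk(1000.0, 914.0) == pytest.approx(9.1, abs=0.05)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            estimate_lar_risk(-1.0, 914.0)


class TestProfile:
    def test_constant_grid(self):
        grid = np.full((11, 11, 11), 3.3)
        d, v = profile_vs_distance(grid, 1.0, -5 * np.ones(3), np.zeros(3),
                                   [0, 0, 1])
        assert np.allclose(v, 3.3)
        assert np.all(np.diff(d) > 0)

    def test_inverse_square_decreases(self):
        n = 21
        ax = np.arange(n) - 10.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        r2 = X**2 + Y**2 + Z**2 + 1.0
        d, v = profile_vs_distance(1.0 / r2, 1.0, np.array([-10.0, -10, -10]),
                                   np.zeros(3), [1, 0, 0])
        assert np.all(np.diff(v) < 0)

    def test_line_exits_immediately(self):
        grid = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            profile_vs_distance(grid, 1.0, np.zeros(3), np.array([100.0, 0, 0]),
                                [1, 0, 0])
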