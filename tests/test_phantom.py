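"""Synthetic phantom, dose model and magnetic-field perturbation generator."""

import dataclasses

import numpy as np
import pytest

from mrplanqa.grid import StructureMask, StructureSet, VoxelGrid
from mrplanqa.phantom import (
    DEFAULT_BEAM_ANGLES,
    Ellipsoid,
    InvalidSpecError,
    NamedGeometry,
    PerturbationParams,
    PhantomSpec,
    Prescription,
    TargetSpec,
    ZCylinder,
    apply_field_perturbation,
    build_phantom,
    compute_noiseless_dose,
    default_perturbations,
    default_spec,
    expected_skin_dmean_increase,
    generate_cohort,
    prescriptions_from_spec,
    simulate_base_dose,
)
from mrplanqa.structures import cavity_interface_shell, derive_standard_regions


class TestPrescription:
    def test_dose_per_fraction_derived(self):
        assert Prescription(69.96, 33).dose_per_fraction_Gy == pytest.approx(2.12)
        assert Prescription(60.06, 33).dose_per_fraction_Gy == pytest.approx(1.82)

    def test_inconsistent_fractionation_rejected(self):
        with pytest.raises(ValueError, match="rounding"):
            Prescription(69.96, 33, dose_per_fraction_Gy=2.0)

    def test_invalid_scalars_rejected(self):
        with pytest.raises(ValueError):
            Prescription(-1.0, 33)
        with pytest.raises(ValueError):
            Prescription(60.0, 0)


class TestBuildPhantom:
    def test_default_phantom_containment(self, default_phantom):
        body = default_phantom["body"]
        ptv = default_phantom["ptv"]
        assert ptv.voxel_count > 0
        assert ptv.issubset(body)
        assert default_phantom["pgtv_tb"].issubset(ptv)
        assert default_phantom["gtv_nd"].issubset(ptv)
        # targets deposit prescribed dose in tissue only
        air = default_phantom["air"]
        assert not (ptv.voxels & air.voxels).any()
        for cavity in ("larynx_trachea", "pharynx"):
            assert default_phantom[cavity].issubset(body)

    def test_deterministic_given_spec(self):
        a = build_phantom(default_spec(seed=3))
        b = build_phantom(default_spec(seed=3))
        assert set(a) == set(b)
        for name in a:
            np.testing.assert_array_equal(a[name].voxels, b[name].voxels)

    def test_cavity_volume_matches_analytic_cylinder(self):
        # r=8 mm, length 60 mm on a 1x1x3 grid: pi r^2 L / (1*1*3) voxels
        spec = dataclasses.replace(
            default_spec(),
            cavity_specs=(
                NamedGeometry("larynx_trachea", ZCylinder((54.0, 44.0), 8.0, 21.0, 81.0)),
            ),
        )
        structs = build_phantom(spec)
        analytic = np.pi * 8.0**2 * 60.0 / 3.0
        # 60 mm extent = 21 slices inclusive at 3-mm pitch; compare against
        # the closed-interval rasterisation (21/20 of the open length)
        count = structs["larynx_trachea"].voxel_count
        assert count == pytest.approx(analytic * 21 / 20, rel=0.05)

    def test_geometry_outside_grid_rejected(self):
        spec = dataclasses.replace(
            default_spec(),
            oar_specs=(
                NamedGeometry("brain_stem", ZCylinder((54.0, 70.0), 6.0, 84.0, 300.0)),
            ),
        )
        with pytest.raises(InvalidSpecError, match="outside the grid"):
            build_phantom(spec)

    def test_target_inside_air_rejected(self):
        high = Prescription(69.96, 33)
        spec = dataclasses.replace(
            default_spec(),
            target_specs=(
                TargetSpec("pgtv_tb", Ellipsoid((54.0, 38.0, 54.0), (3.0, 3.0, 4.0)), high),
            ),
        )
        with pytest.raises(InvalidSpecError, match="inside air"):
            build_phantom(spec)

    def test_cavity_not_in_body_rejected(self):
        spec = dataclasses.replace(
            default_spec(),
            cavity_specs=(
                NamedGeometry("larynx_trachea", ZCylinder((5.0, 5.0), 4.0, 6.0, 99.0)),
            ),
        )
        with pytest.raises(InvalidSpecError, match="not contained"):
            build_phantom(spec)


class TestBaseDose:
    def test_zero_noise_is_deterministic_across_seeds(self, default_phantom, default_rx):
        d1 = simulate_base_dose(default_phantom, default_rx, seed=1, noise_sigma_fraction=0.0)
        d2 = simulate_base_dose(default_phantom, default_rx, seed=99, noise_sigma_fraction=0.0)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_same_seed_reproducible_with_noise(self, default_phantom, default_rx):
        d1 = simulate_base_dose(default_phantom, default_rx, seed=7)
        d2 = simulate_base_dose(default_phantom, default_rx, seed=7)
        np.testing.assert_array_equal(d1.values, d2.values)

    def test_dose_nonnegative_and_zero_outside_body(self, b0_dose, default_phantom):
        assert (b0_dose.values >= 0).all()
        assert not b0_dose.values[~default_phantom["body"].voxels].any()

    def test_target_medians_near_prescription(self, b0_dose, default_phantom, default_rx_gy):
        for name, rx in default_rx_gy.items():
            med = np.median(b0_dose.values[default_phantom[name].voxels])
            assert med == pytest.approx(rx, rel=0.02)

    def test_ptv_coverage_at_prescription(self, b0_dose, default_phantom):
        in_ptv = b0_dose.values[default_phantom["ptv"].voxels]
        v_rx = 100.0 * np.mean(in_ptv >= 60.06)
        assert v_rx >= 90.0

    def test_missing_prescription_is_configuration_error(self, default_phantom, default_rx):
        rx = {k: v for k, v in default_rx.items() if k != "gtv_nd"}
        with pytest.raises(KeyError, match="prescription"):
            simulate_base_dose(default_phantom, rx, seed=1)

    def test_single_beam_depth_dose_monotone_beyond_buildup(self):
        """One beam through a homogeneous cylinder: central-axis dose rises
        in the build-up region, then decreases monotonically with depth."""
        grid = VoxelGrid((81, 81, 11), (1.0, 1.0, 3.0))
        structs = StructureSet(grid)
        X, Y, Z = grid.meshgrid()
        structs.add_array("body", (X - 40) ** 2 + (Y - 40) ** 2 <= 38.0**2)
        structs.add_array("ptv", (X - 40) ** 2 + (Y - 40) ** 2 + (Z - 15) ** 2 <= 10.0**2)
        dose = compute_noiseless_dose(
            structs,
            {"ptv": Prescription(60.06, 33)},
            beam_angles_deg=[0.0],
            modulation=0.0,
            conformity=0.0,
        )
        # beam travels along +x; entry at x = 2; profile on the central axis
        profile = dose.values[2:79, 40, 5]
        beyond_buildup = profile[13:]
        assert np.all(np.diff(beyond_buildup) <= 1e-9)
        assert profile[0] < profile.max()


class TestPerturbation:
    def test_zero_params_identity(self, b0_dose, default_phantom):
        params = PerturbationParams(noise_sigma_fraction=0.0)
        out = apply_field_perturbation(b0_dose, default_phantom, params, "B15_RECAL")
        np.testing.assert_array_equal(out.values, b0_dose.values)

    def test_b0_returns_input_unchanged(self, b0_dose, default_phantom):
        params = default_perturbations()["B15_RECAL"]
        out = apply_field_perturbation(b0_dose, default_phantom, params, "B0")
        np.testing.assert_array_equal(out.values, b0_dose.values)

    def test_unknown_condition_rejected(self, b0_dose, default_phantom):
        with pytest.raises(ValueError, match="unknown plan condition"):
            apply_field_perturbation(
                b0_dose, default_phantom, PerturbationParams(), "B30"
            )

    def test_skin_boost_mean_equals_brute_force_voxel_sum(self):
        """Mean skin-shell increase = A * mean(exp(-d/lambda) * sector) by
        direct voxel summation on a small isotropic grid."""
        grid = VoxelGrid((40, 40, 40), (1.0, 1.0, 1.0))
        structs = StructureSet(grid)
        X, Y, Z = grid.meshgrid()
        body = (X - 20) ** 2 + (Y - 20) ** 2 <= 15.0**2
        structs.add_array("body", body)
        structs.add_array("ptv", (X - 20) ** 2 + (Y - 20) ** 2 <= 4.0**2)
        derive_standard_regions(structs)
        params = PerturbationParams(
            skin_boost_amplitude_Gy=2.0, skin_decay_length_mm=5.0,
            noise_sigma_fraction=0.0,
        )
        base = VoxelGrid((40, 40, 40), (1.0, 1.0, 1.0))
        dose0 = simulate_base_dose(structs, {"ptv": Prescription(60.06, 33)}, 1,
                                   noise_sigma_fraction=0.0)
        out = apply_field_perturbation(dose0, structs, params, "B15_REOPT")
        skin = structs["skin"].voxels
        measured = (out.values[skin] - dose0.values[skin]).mean()

        from scipy import ndimage

        from mrplanqa.phantom import _sector_on

        # lateral depth below the body outline (scan edges carry no skin)
        padded = np.pad(body, ((1, 1), (1, 1), (0, 0)), constant_values=False)
        d = ndimage.distance_transform_edt(padded, sampling=(1.0, 1.0, 1.0))[1:-1, 1:-1, :]
        on = _sector_on(structs)[:, :, None] & body
        brute = 2.0 * (np.exp(-d / 5.0) * on)[skin].mean()
        assert measured == pytest.approx(brute, rel=1e-9)
        assert expected_skin_dmean_increase(structs, params) == pytest.approx(brute)

    def test_skin_boost_sectors_cover_at_least_half_circumference(self, default_phantom):
        from mrplanqa.phantom import _sector_on

        on = _sector_on(default_phantom)
        skin2d = default_phantom["skin"].voxels.any(axis=2)
        assert on[skin2d].mean() >= 0.5

    def test_cavity_shift_antisymmetric_near_cancellation(self, b0_dose, default_phantom):
        """The +B/-B interface perturbation moves the full two-sided shell
        mean by far less than B."""
        params = PerturbationParams(
            cavity_shift_amplitude_Gy=2.0, noise_sigma_fraction=0.0
        )
        out = apply_field_perturbation(b0_dose, default_phantom, params, "B15_REOPT")
        for cavity in ("larynx_trachea", "pharynx"):
            shell = default_phantom[f"{cavity}_interface"].voxels
            delta = (out.values[shell] - b0_dose.values[shell]).mean()
            assert abs(delta) < 0.05 * 2.0

    def test_coverage_degradation_only_under_recal(self, b0_dose, default_phantom):
        params = PerturbationParams(
            coverage_degradation=0.03, noise_sigma_fraction=0.0
        )
        recal = apply_field_perturbation(b0_dose, default_phantom, params, "B15_RECAL")
        ptv = default_phantom["ptv"].voxels
        np.testing.assert_allclose(recal.values[ptv], b0_dose.values[ptv] * 0.97)
        np.testing.assert_array_equal(recal.values[~ptv], b0_dose.values[~ptv])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PerturbationParams(skin_boost_amplitude_Gy=-1.0)
        with pytest.raises(ValueError):
            PerturbationParams(cavity_shift_direction=(0.0, 0.0))
        with pytest.raises(ValueError):
            PerturbationParams(coverage_degradation=1.5)

    def test_direction_normalised(self):
        p = PerturbationParams(cavity_shift_direction=(3.0, 4.0))
        assert p.cavity_shift_direction == pytest.approx((0.6, 0.8))


class TestGenerateCohort:
    def test_reproducible_given_master_seed(self):
        c1 = generate_cohort(2, 42)
        c2 = generate_cohort(2, 42)
        for (s1, d1), (s2, d2) in zip(c1, c2):
            for name in s1:
                np.testing.assert_array_equal(s1[name].voxels, s2[name].voxels)
            for cond in d1:
                np.testing.assert_array_equal(d1[cond].values, d2[cond].values)

    def test_patients_vary_anatomically(self):
        cohort = generate_cohort(3, 0)
        counts = [structs["ptv"].voxel_count for structs, _ in cohort]
        assert len(set(counts)) > 1

    def test_single_patient_degenerate_cohort(self):
        cohort = generate_cohort(1, 5)
        assert len(cohort) == 1
        structs, doses = cohort[0]
        assert set(doses) == {"B0", "B15_RECAL", "B15_REOPT"}
        assert "skin" in structs and "normal_tissue" in structs

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 1)

    def test_skin_dmean_recovery_of_configured_amplitude(self):
        """Cohort-mean skin shift recovers the configured amplitude mapping
        within 10% relative error over many patients."""
        n = 20
        cohort = generate_cohort(n, 7)
        params = default_perturbations()["B15_RECAL"]
        measured, expected = [], []
        for structs, doses in cohort:
            skin = structs["skin"].voxels
            measured.append(
                doses["B15_RECAL"].values[skin].mean() - doses["B0"].values[skin].mean()
            )
            expected.append(expected_skin_dmean_increase(structs, params))
        assert np.mean(measured) == pytest.approx(np.mean(expected), rel=0.10)
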