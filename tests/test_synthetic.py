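"""Synthetic phantom: porosity/BMD fields, CT and two-pool MR rendering."""

import numpy as np
import pytest

from utepi import PhantomSpec, compute_pi
from utepi.synthetic import (generate_study, iter_study, make_bmd_field,
                             make_porosity_field,
                             pi_closed_form, render_ct, render_mr_echoes,
                             two_pool_signal)
from utepi.volume import AffineTransform


@pytest.fixture(scope="module")
def tiny_spec():
    return PhantomSpec.scaled(0.45, seed=5)


class TestSpecValidation:
    def test_te_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(te_short_ms=2.52, te_long_ms=2.52)

    def test_t2s_ordering_enforced(self):
        with pytest.raises(ValueError):
            PhantomSpec(t2s_bound_ms=10.0, t2s_pore_ms=0.39)

    def test_non_positive_t2s_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(t2s_bound_ms=-1.0)

    def test_needs_two_distinct_insert_densities(self):
        with pytest.raises(ValueError):
            PhantomSpec(insert_densities=(200.0, 200.0))

    def test_shell_must_fit_in_cap(self):
        with pytest.raises(ValueError):
            PhantomSpec(shell_thickness_mm=10.0, cap_radius_mm=8.5)


class TestPorosityField:
    def test_degenerate_variation_gives_exact_levels(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, phi_variation=0.0)
        phi, masks = make_porosity_field(spec)
        shell = masks["shell"].values
        core = masks["core"].values
        assert np.all(phi.values[shell] == spec.phi_cortical)
        assert np.all(phi.values[core] == spec.phi_trabecular)
        assert np.all(phi.values[~masks["bone"].values] == 0.0)

    def test_equal_levels_give_constant_field(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, phi_cortical=0.3, phi_trabecular=0.3,
                       phi_variation=0.0)
        phi, masks = make_porosity_field(spec)
        assert np.all(phi.values[masks["bone"].values] == 0.3)

    def test_shell_mean_near_cortical_level(self, tiny_spec):
        phi, masks = make_porosity_field(tiny_spec)
        shell_mean = phi.values[masks["shell"].values].mean()
        assert abs(shell_mean - tiny_spec.phi_cortical) < 0.02

    def test_field_bounded_and_condyle_inside_bone(self, tiny_spec):
        phi, masks = make_porosity_field(tiny_spec)
        assert phi.values.min() >= 0.0 and phi.values.max() <= 1.0
        assert not np.any(masks["condyle"].values & ~masks["bone"].values)


class TestBMDField:
    def test_zero_porosity_zero_noise_gives_rho_max(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, phi_cortical=0.0, phi_trabecular=0.0,
                       phi_variation=0.0, bmd_noise_sd=0.0)
        phi, masks = make_porosity_field(spec)
        bmd = make_bmd_field(phi, spec, masks["bone"])
        assert np.all(bmd.values[masks["bone"].values] == spec.rho_max)

    def test_noiseless_coupling_gives_perfect_anticorrelation(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, bmd_noise_sd=0.0)
        phi, masks = make_porosity_field(spec)
        bmd = make_bmd_field(phi, spec, masks["bone"])
        bone = masks["bone"].values
        r = np.corrcoef(phi.values[bone], bmd.values[bone])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_noise_attenuates_r_by_analytic_factor(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, bmd_noise_sd=40.0)
        phi, masks = make_porosity_field(spec)
        bmd = make_bmd_field(phi, spec, masks["bone"])
        bone = masks["bone"].values
        r = np.corrcoef(phi.values[bone], bmd.values[bone])[0, 1]
        signal_sd = spec.rho_max * spec.coupling * phi.values[bone].std()
        expected = -1.0 / np.sqrt(1.0 + (spec.bmd_noise_sd / signal_sd) ** 2)
        assert r == pytest.approx(expected, abs=0.05)


class TestRenderCT:
    def test_identity_grey_model_reproduces_bmd(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, g0=0.0, g1=1.0, ct_noise_sd=0.0)
        phi, masks = make_porosity_field(spec)
        bmd = make_bmd_field(phi, spec, masks["bone"])
        ct, _ = render_ct(bmd, spec, masks["bone"])
        bone = masks["bone"].values
        assert np.allclose(ct.values[bone], bmd.values[bone])

    def test_water_insert_mean_grey_equals_offset(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, ct_noise_sd=0.0)
        phi, masks = make_porosity_field(spec)
        bmd = make_bmd_field(phi, spec, masks["bone"])
        ct, inserts = render_ct(bmd, spec, masks["bone"])
        water = [m for m, d in inserts if d == 0.0][0]
        assert ct.values[water.values].mean() == pytest.approx(spec.g0)

    def test_two_point_insert_fit_recovers_grey_model(self, tiny_spec):
        # noiseless rods at densities (0, d): the line through their mean
        # greys inverts to exactly (1/g1, -g0/g1)
        from dataclasses import replace
        spec = replace(tiny_spec, ct_noise_sd=0.0)
        phi, masks = make_porosity_field(spec)
        bmd = make_bmd_field(phi, spec, masks["bone"])
        ct, inserts = render_ct(bmd, spec, masks["bone"])
        greys = np.array([ct.values[m.values].mean() for m, _ in inserts])
        dens = np.array([d for _, d in inserts])
        slope = (dens[-1] - dens[0]) / (greys[-1] - greys[0])
        assert slope == pytest.approx(1.0 / spec.g1, rel=1e-9)
        assert dens[0] - slope * greys[0] == pytest.approx(-spec.g0 / spec.g1, rel=1e-9)


class TestTwoPoolModel:
    def test_pure_bound_water_closed_form(self):
        # phi=0: PI = 100 exp(-(TE_l - TE_s)/T2*_BW) = 100 exp(-2.48/0.39)
        spec = PhantomSpec()
        assert pi_closed_form(0.0, spec) == pytest.approx(
            100.0 * np.exp(-2.48 / 0.39), rel=1e-12)
        assert pi_closed_form(0.0, spec) == pytest.approx(0.173, abs=5e-4)

    def test_pure_pore_water_closed_form(self):
        spec = PhantomSpec()
        assert pi_closed_form(1.0, spec) == pytest.approx(
            100.0 * np.exp(-2.48 / 10.0), rel=1e-12)
        assert pi_closed_form(1.0, spec) == pytest.approx(78.04, abs=0.01)

    def test_pi_strictly_increasing_in_porosity(self):
        spec = PhantomSpec()
        phi = np.linspace(0, 1, 101)
        pi = pi_closed_form(phi, spec)
        assert np.all(np.diff(pi) > 0)

    def test_signal_is_two_exponential_mixture(self):
        spec = PhantomSpec()
        s = two_pool_signal(0.25, 1.0, spec)
        expected = 0.75 * np.exp(-1.0 / spec.t2s_bound_ms) \
            + 0.25 * np.exp(-1.0 / spec.t2s_pore_ms)
        assert s == pytest.approx(expected, rel=1e-12)


class TestRenderEchoes:
    def test_noiseless_aligned_pi_matches_closed_form(self, tiny_spec):
        from dataclasses import replace
        spec = replace(tiny_spec, mr_noise_sd=0.0, phi_variation=0.0,
                       misalignment=AffineTransform.identity())
        phi, masks = make_porosity_field(spec)
        e1, e2 = render_mr_echoes(phi, spec, masks["bone"])
        pi = compute_pi(e1, e2, floor=0.5)
        # deep-core MR voxels (away from shell partial volume)
        vals = pi.values.values
        core_pi = pi_closed_form(spec.phi_trabecular, spec)
        sel = ~np.isnan(vals) & (np.abs(vals - core_pi) < 5.0)
        assert sel.sum() > 50
        assert np.nanmedian(vals[sel]) == pytest.approx(core_pi, abs=0.5)

    def test_echo_volumes_live_on_mr_grid(self, tiny_spec):
        phi, masks = make_porosity_field(tiny_spec)
        e1, e2 = render_mr_echoes(phi, tiny_spec, masks["bone"])
        assert e1.shape == tuple(tiny_spec.mr_shape)
        assert np.allclose(e1.spacing, tiny_spec.mr_spacing)
        assert e1.same_geometry(e2)


class TestStudyGeneration:
    def test_study_shape_and_manifest(self, tmp_path):
        spec = PhantomSpec.scaled(0.35, seed=1)
        bundles = generate_study(n_horses=2, spec=spec, seed=4,
                                 out_dir=tmp_path / "study")
        assert len(bundles) == 8
        manifest = (tmp_path / "study" / "manifest.csv").read_text().strip().splitlines()
        assert len(manifest) == 9  # header + 8 rows
        assert (tmp_path / "study" / "horse1_LF" / "ct.nii.gz").exists()

    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec.scaled(0.35, seed=1)
        a = next(iter_study(1, spec=spec, seed=9))
        b = next(iter_study(1, spec=spec, seed=9))
        assert np.array_equal(a.ct.values, b.ct.values)
        assert np.array_equal(a.echo1.values, b.echo1.values)
        assert a.truth.true_r == b.truth.true_r

    def test_excluded_limb_flagged_not_dropped(self):
        spec = PhantomSpec.scaled(0.35, seed=1)
        bundles = generate_study(n_horses=1, spec=spec, seed=2,
                                 overrides={("horse1", "RF"): {"excluded": True}})
        assert len(bundles) == 4
        flags = {b.limb: b.excluded for b in bundles}
        assert flags == {"LF": False, "RF": True, "LH": False, "RH": False}

    def test_duplicate_limb_labels_rejected(self):
        with pytest.raises(ValueError):
            list(iter_study(1, limbs=("LF", "LF")))

    def test_per_limb_overrides_change_spec(self):
        spec = PhantomSpec.scaled(0.35, seed=1)
        bundles = generate_study(n_horses=1, spec=spec, seed=2,
                                 overrides={"LH": {"mr_noise_sd": 0.2}})
        by_limb = {b.limb: b for b in bundles}
        assert by_limb["LH"].spec.mr_noise_sd == 0.2
        assert by_limb["LF"].spec.mr_noise_sd == spec.mr_noise_sd

    def test_unknown_override_key_rejected(self):
        with pytest.raises(ValueError):
            list(iter_study(1, overrides={"LF": {"not_a_field": 1}}))


class TestGroundTruthInvariants:
    def test_truth_r_negative_and_transform_inverts_misalignment(self, half_specimen):
        b = half_specimen
        assert b.truth.true_r < 0
        ident = b.truth.transform.compose(b.spec.misalignment)
        assert np.allclose(ident.matrix, np.eye(3), atol=1e-9)
        assert np.allclose(ident.translation, 0, atol=1e-9)

    def test_insert_masks_disjoint_from_bone(self, half_specimen):
        b = half_specimen
        for mask, _ in b.truth.insert_masks:
            assert not np.any(mask.values & b.truth.bone_mask.values)
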