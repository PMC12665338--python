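"""Generator-level checks: geometry, signal model, noise, determinism."""

import numpy as np
import pytest

from dtiabv.grids import Grid
from dtiabv.phantom import (EffectSpec, GradientTable, PhantomSpec, arc_tract,
                            build_cohort, build_tensor_phantom,
                            default_effects, erosion_weights,
                            fa_of_eigenvalues, simulate_dwi, straight_tract,
                            tensors_from_fa_md)


class TestGradientTable:
    def test_default_scheme_is_valid(self, gtab):
        assert gtab.n_directions == 31
        assert (gtab.bvals == 0).sum() == 1
        norms = np.linalg.norm(gtab.bvecs[gtab.bvals > 0], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    @pytest.mark.parametrize("bvals,bvecs", [
        ([0, 1000], [[0, 0, 0], [1, 1, 0]]),            # non-unit direction
        ([1000] * 7, [[1, 0, 0]] * 7),                  # no b=0
        ([0, 1000, 1000], [[0, 0, 0], [1, 0, 0], [0, 1, 0]]),  # < 6 directions
    ])
    def test_invalid_tables_rejected(self, bvals, bvecs):
        with pytest.raises(ValueError):
            GradientTable(np.array(bvals, float), np.array(bvecs, float))

    def test_fsl_round_trip(self, gtab, tmp_path):
        gtab.save(tmp_path / "d.bval", tmp_path / "d.bvec")
        back = GradientTable.load(tmp_path / "d.bval", tmp_path / "d.bvec")
        np.testing.assert_allclose(back.bvals, gtab.bvals)
        np.testing.assert_allclose(back.bvecs, gtab.bvecs, atol=1e-7)


class TestTensorPhantom:
    def test_straight_tract_principal_axis(self, straight_anatomy):
        tf = straight_anatomy.tensor_field()
        mask = straight_anatomy.tract_masks["rod"]
        _, vecs = np.linalg.eigh(tf.data[mask])
        principal = np.abs(vecs[:, :, 2])
        np.testing.assert_allclose(principal, np.tile([1.0, 0, 0], (mask.sum(), 1)),
                                   atol=1e-12)

    def test_zero_tracts_gives_isotropic_field(self):
        spec = PhantomSpec(grid=Grid((16, 16, 16), (2, 2, 2)),
                           brain_semi_axes_mm=(14, 14, 14))
        anatomy = build_tensor_phantom(spec)
        assert anatomy.base_fa.max() == 0.0
        ev = anatomy.tensor_field().eigenvalues()
        inside = anatomy.brain_mask
        np.testing.assert_allclose(ev[inside], spec.background_diffusivity,
                                   rtol=1e-12)

    def test_curved_tract_follows_analytic_tangent(self):
        grid = Grid((40, 40, 24), (2.0, 2.0, 2.0))
        center = np.array([10.0, 10.0, 23.0])
        spec = PhantomSpec(grid=grid,
                           tracts=(arc_tract("arc", center, 24.0, 5.0,
                                             0.0, 90.0, plane="xy"),),
                           brain_semi_axes_mm=(60, 60, 60))
        anatomy = build_tensor_phantom(spec)
        mask = anatomy.tract_masks["arc"]
        assert mask.sum() > 100
        centers = grid.voxel_centers_mm()[mask]
        radial = centers - center
        radial[:, 2] = 0.0
        # end-cap voxels project beyond the arc; the analytic tangent is
        # defined only over the swept angular range
        theta = np.degrees(np.arctan2(radial[:, 1], radial[:, 0]))
        interior = (theta > 2.0) & (theta < 88.0)
        analytic = np.cross(np.array([0.0, 0.0, 1.0]), radial)
        analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
        analytic = analytic[interior]
        got = anatomy.tangents[mask][interior]
        cos = np.abs((got * analytic).sum(axis=1))
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert angles.max() < 5.0

    def test_overlapping_conflicting_tracts_rejected(self):
        grid = Grid((24, 24, 24), (2.0, 2.0, 2.0))
        spec = PhantomSpec(
            grid=grid,
            tracts=(straight_tract("a", (4, 23, 23), (42, 23, 23), 6.0),
                    straight_tract("b", (23, 4, 23), (23, 42, 23), 6.0)),
            brain_semi_axes_mm=(30, 30, 30))
        with pytest.raises(ValueError, match="conflicting orientation"):
            build_tensor_phantom(spec)
        anatomy = build_tensor_phantom(spec, blend="first")
        overlap = anatomy.tract_masks["a"] & anatomy.tract_masks["b"]
        np.testing.assert_allclose(anatomy.tangents[overlap],
                                   np.tile([1.0, 0, 0], (overlap.sum(), 1)))

    def test_probability_maps_bounded(self, default_anatomy):
        total = default_anatomy.gm + default_anatomy.wm + default_anatomy.csf
        assert total.max() <= 1.0 + 1e-12
        assert (total[~default_anatomy.brain_mask] == 0).all()

    def test_structure_volumes_match_geometry(self, default_spec, default_anatomy):
        # ellipsoid volume vs voxelized mask within one voxel-shell tolerance
        for s in default_spec.structures:
            analytic = 4 / 3 * np.pi * np.prod(s.semi_axes_mm)
            voxel = default_anatomy.structure_masks[s.name].sum() * 8.0
            assert abs(voxel - analytic) / analytic < 0.25


class TestSignalModel:
    def test_isotropic_attenuation_closed_form(self, gtab):
        d = 1e-3 * np.eye(3)
        sig = simulate_dwi(d[None, :, :], gtab, s0=1000.0)
        dw = gtab.bvals > 0
        np.testing.assert_allclose(sig[0, dw] / 1000.0, np.exp(-1.0), rtol=1e-12)
        np.testing.assert_allclose(sig[0, ~dw], 1000.0)

    def test_b0_independent_of_tensor(self, gtab):
        rng = np.random.default_rng(0)
        a = rng.random((5, 3, 3))
        d = (a + a.transpose(0, 2, 1)) * 1e-3
        sig = simulate_dwi(d, gtab, s0=500.0)
        np.testing.assert_allclose(sig[:, gtab.bvals == 0], 500.0)

    def test_nonpositive_s0_rejected(self, gtab):
        with pytest.raises(ValueError, match="s0"):
            simulate_dwi(np.eye(3)[None], gtab, s0=0.0)

    def test_rician_mean_matches_closed_form(self, gtab):
        s0, sigma_rel = 1000.0, 0.02
        d = 0.7e-3 * np.eye(3)
        rng = np.random.default_rng(42)
        reps = simulate_dwi(np.broadcast_to(d, (10000, 3, 3)), gtab,
                            s0=s0, noise_sigma=sigma_rel, rng=rng)
        sigma = sigma_rel * s0
        noiseless = simulate_dwi(d[None], gtab, s0=s0)[0]
        # E|S| = sigma*sqrt(pi/2)*L_{1/2}(-x) with x = nu^2/(2 sigma^2);
        # written with exponentially scaled Bessels to survive high SNR
        from scipy.special import i0e, i1e
        x = (noiseless / sigma) ** 2 / 2.0
        expected = sigma * np.sqrt(np.pi / 2) * ((1 + x) * i0e(x / 2)
                                                 + x * i1e(x / 2))
        np.testing.assert_allclose(reps.mean(axis=0), expected, rtol=0.01)


class TestEffectInjection:
    def test_fa_md_retargeting_closed_form(self):
        # axially symmetric construction hits any requested FA at fixed MD
        fa_req = np.array([0.0, 0.2, 0.5, 0.8, 0.95])
        d = tensors_from_fa_md(fa_req, 0.7e-3, np.array([0.0, 1.0, 0.0]))
        ev = np.linalg.eigvalsh(d)
        np.testing.assert_allclose(fa_of_eigenvalues(ev), fa_req, atol=1e-12)
        np.testing.assert_allclose(ev.mean(axis=-1), 0.7e-3, rtol=1e-12)

    def test_noiseless_reduction_calibration(self, default_spec, default_anatomy):
        effects = EffectSpec(fa_reduction={"genu_cc": {"bvFTD": 0.15}})
        cohort = build_cohort(default_spec, effects,
                              {"control": 2, "bvFTD": 2}, seed=5,
                              anatomy=default_anatomy)
        mask = default_anatomy.tract_masks["genu_cc"]
        fa_ctrl = cohort.target_fa(cohort.table.iloc[0])
        fa_pat = cohort.target_fa(cohort.table.iloc[2])
        realized = 1.0 - fa_pat[mask].mean() / fa_ctrl[mask].mean()
        assert abs(realized - 0.15) < 1e-3

    def test_noisy_cohort_reduction_recovered(self, default_spec, default_anatomy):
        effects = EffectSpec(fa_reduction={"corticospinal_R": {"bvFTD": 0.15}},
                             noise_sigma=0.02)
        cohort = build_cohort(default_spec, effects,
                              {"control": 6, "bvFTD": 6}, seed=5,
                              anatomy=default_anatomy)
        fa, _ = cohort.fa_md_maps()
        mask = default_anatomy.tract_masks["corticospinal_R"]
        ctrl = fa[:6][:, mask].mean()
        pat = fa[6:][:, mask].mean()
        assert pat / ctrl == pytest.approx(0.85, abs=0.02)

    def test_unknown_effect_names_rejected(self, default_spec):
        effects = EffectSpec(fa_reduction={"no_such_tract": {"bvFTD": 0.1}},
                             volume_atrophy={"no_such_soi": {"bvFTD": 0.1}})
        with pytest.raises(ValueError) as err:
            build_cohort(default_spec, effects, {"control": 2, "bvFTD": 2}, seed=0)
        assert "no_such_tract" in str(err.value)
        assert "no_such_soi" in str(err.value)

    def test_erosion_hits_exact_fraction(self, straight_anatomy):
        mask = straight_anatomy.structure_masks["blob"]
        for frac in (0.05, 0.2, 0.5):
            w = erosion_weights(mask, frac)
            assert w[mask].sum() == pytest.approx((1 - frac) * mask.sum(), abs=1e-9)
            # boundary removed before the core
            from scipy.ndimage import distance_transform_edt
            depth = distance_transform_edt(mask)
            assert depth[w == 1.0].min() >= depth[mask & (w == 0.0)].max() - 1e-9

    def test_erosion_with_density_hits_mass_fraction(self, straight_anatomy):
        mask = straight_anatomy.structure_masks["blob"]
        rng = np.random.default_rng(0)
        density = rng.uniform(0.2, 0.9, mask.shape)
        w = erosion_weights(mask, 0.3, density=density)
        kept = (density * w)[mask].sum()
        assert kept == pytest.approx(0.7 * density[mask].sum(), rel=1e-12)


class TestCohortDeterminism:
    def test_same_seed_bit_identical(self, default_spec, default_anatomy):
        effects = default_effects()
        kw = dict(n_per_group={"control": 3, "bvFTD": 3}, seed=11,
                  n_followup=2, anatomy=default_anatomy)
        a = build_cohort(default_spec, effects, **kw)
        b = build_cohort(default_spec, effects, **kw)
        assert a.table.equals(b.table)
        for i in (0, 4, 7):
            assert np.array_equal(a.subject_signal(i), b.subject_signal(i))
            ca, cb = a.subject_compartments(i), b.subject_compartments(i)
            for key in ("gm", "wm", "csf"):
                assert np.array_equal(ca[key], cb[key])

    def test_different_seed_differs(self, default_spec, default_anatomy):
        effects = default_effects()
        a = build_cohort(default_spec, effects, {"control": 2, "bvFTD": 2},
                         seed=1, anatomy=default_anatomy)
        b = build_cohort(default_spec, effects, {"control": 2, "bvFTD": 2},
                         seed=2, anatomy=default_anatomy)
        assert not np.array_equal(a.subject_signal(0), b.subject_signal(0))

    def test_followup_rows_reference_baseline(self, default_spec, default_anatomy):
        cohort = build_cohort(default_spec, default_effects(),
                              {"control": 2, "bvFTD": 3}, seed=0, n_followup=2,
                              anatomy=default_anatomy)
        fu = cohort.table[cohort.table.timepoint == "followup"]
        base_ids = set(cohort.table[cohort.table.timepoint == "baseline"].subject)
        assert set(fu.subject) <= base_ids
        assert (fu.group == "bvFTD").all()

    def test_small_group_rejected(self, default_spec):
        with pytest.raises(ValueError, match=">= 2"):
            build_cohort(default_spec, EffectSpec(), {"control": 1}, seed=0)
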