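import itertools

import numpy as np
import pytest

from rtnf.mapglm import (
    StatMap,
    build_lsa_design,
    cluster_threshold,
    conjunction,
    default_contrasts,
    disjunction,
    first_level_lsa,
    gaussian_smooth,
    group_one_sample,
    highpass,
    max_cluster_null,
    motion_exclude,
    t_to_z,
)
from rtnf.synthetic import SimulationParams, simulate_volume_run

GRID = (6, 6, 6)


def _cube_layout(amplitude=3.0):
    cube = np.zeros(GRID, bool)
    cube[1:4, 1:4, 1:4] = True
    return {"target": (cube, {"think": amplitude})}, cube


def _subject_copes(schedule, layout, n_subjects, noise_sd=0.5, seed0=100,
                   contrast="think"):
    maps = []
    for s in range(n_subjects):
        run = simulate_volume_run(
            GRID, layout, schedule,
            SimulationParams(noise_sd=noise_sd, drift_amplitude=0.0, global_sd=0.0),
            seed=seed0 + s,
        )
        maps.append(first_level_lsa(run.volume4d, schedule).copes[contrast])
    return maps


class TestPreprocessing:
    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.standard_normal(GRID)
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0), vol)

    def test_delta_becomes_sampled_gaussian(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        fwhm, voxel = 8.0, (2.0, 2.0, 2.0)
        out = gaussian_smooth(vol, fwhm, voxel)
        sigma_vox = fwhm / 2.354820045 / voxel[0]
        x = (np.arange(21) - 10.0)
        expected_profile = np.exp(-(x**2) / (2 * sigma_vox**2))
        profile = out[:, 10, 10] / out[10, 10, 10]
        np.testing.assert_allclose(profile, expected_profile, atol=0.01)

    def test_interior_delta_conserves_sum(self):
        vol = np.zeros((25, 25, 25))
        vol[12, 12, 12] = 3.0
        out = gaussian_smooth(vol, 8.0, (2.0, 2.0, 2.0))
        assert out.sum() == pytest.approx(3.0, abs=1e-6)

    def test_highpass_removes_linear_drift(self):
        n, tr = 185, 2.0
        drift = np.linspace(0, 10, n)
        out = highpass(drift, 0.01, tr)
        assert np.abs(out).max() < 0.01 * np.ptp(drift)

    def test_highpass_preserves_fast_sinusoid(self):
        n, tr = 185, 2.0
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * 0.05 * t)
        out = highpass(x, 0.01, tr)
        ratio = np.ptp(out[20:-20]) / np.ptp(x[20:-20])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_highpass_constant_to_zero_and_bad_cutoff(self):
        np.testing.assert_allclose(highpass(np.full(50, 7.0), 0.01, 2.0), 0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            highpass(np.zeros(50), 0.5, 2.0)


class TestMotionExclusion:
    def test_identical_correlations_exclude_nobody(self, parallel, rng):
        task = rng.standard_normal(185)
        disp = rng.standard_normal(185)
        records = [(f"s{i}", disp) for i in range(6)]
        out = motion_exclude(records, task)
        assert not any(m.excluded for m in out)

    def test_single_outlier_excluded(self, parallel, rng):
        """19 subjects with small displacement/task correlations, one with
        r = 0.9: the fence Q1 + 1.5*IQR isolates exactly the mover."""
        from rtnf.efficiency import condition_regressor

        task = condition_regressor(parallel, "think")
        task_u = (task - task.mean()) / np.linalg.norm(task - task.mean())
        noise = rng.standard_normal(185)
        noise -= noise.mean()
        noise -= (noise @ task_u) * task_u
        noise /= np.linalg.norm(noise)

        def trace_with_r(r):
            return r * task_u + np.sqrt(1 - r**2) * noise

        target_rs = [-0.02] * 10 + [0.02] * 9  # fence = -0.02 + 1.5*0.04 = 0.04
        records = [(f"s{i}", trace_with_r(r)) for i, r in enumerate(target_rs)]
        records.append(("mover", trace_with_r(0.9)))
        out = motion_exclude(records, task)
        excluded = [m.subject for m in out if m.excluded]
        assert excluded == ["mover"]

    def test_constant_displacement_flagged_for_review(self, rng):
        task = rng.standard_normal(50)
        records = [("a", rng.standard_normal(50)) for _ in range(4)]
        records.append(("flat", np.zeros(50)))
        out = motion_exclude(records, task)
        flat = [m for m in out if m.subject == "flat"][0]
        assert flat.needs_review and not flat.excluded

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            motion_exclude([("a", rng.standard_normal(10))] * 3, rng.standard_normal(10))


class TestFirstLevelDesign:
    def test_parallel_has_six_think_repetitions(self, parallel):
        names, X, interest = build_lsa_design(parallel)
        thinks = [n for n in names if n.startswith("think_")
                  and not n.endswith("deriv")]
        assert len(thinks) == 6
        assert "count" in names and "feedback" not in names
        assert X.shape[0] == 185

    def test_serial_has_eight_think_reps_and_feedback(self, serial):
        names, _, _ = build_lsa_design(serial)
        thinks = [n for n in names if n.startswith("think_")
                  and not n.endswith("deriv")]
        assert len(thinks) == 8
        assert "feedback" in names

    def test_motion_confounds_extended_to_24(self, serial, rng):
        mp = rng.standard_normal((185, 6))
        names, X, _ = build_lsa_design(serial, mp, extended_motion=True)
        assert sum(n.startswith("motion_") for n in names) == 24
        names6, _, _ = build_lsa_design(serial, mp, extended_motion=False)
        assert sum(n.startswith("motion_") for n in names6) == 6

    def test_contrast_positive_weights_sum_to_1(self, parallel, serial):
        for sched in (parallel, serial):
            names, _, _ = build_lsa_design(sched)
            for cname, w in default_contrasts(sched, names).items():
                assert w[w > 0].sum() == pytest.approx(1.0)
                # count enters every contrast at weight -1
                assert w[names.index("count")] == -1.0
                deriv_idx = [i for i, n in enumerate(names) if n.endswith("deriv")]
                assert np.all(w[deriv_idx] == 0)


class TestFirstLevelFit:
    def test_betas_match_per_voxel_brute_force(self, parallel):
        layout, cube = _cube_layout()
        run = simulate_volume_run(
            GRID, layout, parallel,
            SimulationParams(noise_sd=0.3, drift_amplitude=0.0, global_sd=0.0),
            seed=0,
        )
        res = first_level_lsa(run.volume4d, parallel)
        _, X, _ = build_lsa_design(parallel)
        for v in [(0, 0, 0), (2, 2, 2), (5, 1, 3)]:
            brute = np.linalg.lstsq(X, run.volume4d[v], rcond=None)[0]
            np.testing.assert_allclose(res.betas[:, v[0], v[1], v[2]], brute,
                                       atol=1e-8)

    def test_z_map_maximal_inside_active_cube(self, parallel, clean_params):
        layout, cube = _cube_layout()
        run = simulate_volume_run(GRID, layout, parallel, clean_params, seed=0)
        z = first_level_lsa(run.volume4d, parallel).zmaps["think"].values
        assert z[cube].min() > z[~cube].max()

    def test_lsa_average_equals_single_regressor_beta(self, parallel):
        """On a noise-free series whose response matches the model
        hemodynamics, the mean of the per-repetition betas equals the
        single-regressor beta."""
        from rtnf.efficiency import build_design, fit_ols

        d = build_design(parallel, ["think"])
        ts = 500.0 + 12.0 * d.column("think")
        vol = np.broadcast_to(ts, GRID + (185,)).copy()
        res = first_level_lsa(vol, parallel)
        think_idx = [i for i, n in enumerate(res.names)
                     if n.startswith("think_") and not n.endswith("deriv")]
        lsa_mean = res.betas[think_idx, 2, 2, 2].mean()
        beta, _ = fit_ols(d, ts)
        assert lsa_mean == pytest.approx(beta[0], abs=1e-6)


class TestGroupAndClusters:
    def test_identical_maps_give_capped_z(self, parallel):
        m = StatMap(np.ones(GRID), np.ones(GRID, bool), stat_type="contrast")
        z = group_one_sample([m, m, m])
        assert z.values.min() > 8

    def test_sign_flip_antisymmetry(self, parallel, rng):
        maps = [StatMap(rng.standard_normal(GRID), np.ones(GRID, bool)) for _ in range(5)]
        neg = [StatMap(-m.values, m.mask) for m in maps]
        np.testing.assert_allclose(
            group_one_sample(neg).values, -group_one_sample(maps).values, atol=1e-10
        )

    def test_group_needs_three_maps(self):
        m = StatMap(np.zeros(GRID), np.ones(GRID, bool))
        with pytest.raises(ValueError):
            group_one_sample([m, m])

    def test_subthreshold_map_yields_empty_result(self):
        zmap = StatMap(np.full(GRID, 1.0), np.ones(GRID, bool))
        thr, table = cluster_threshold(zmap, z_form=3.1, alpha=0.05)
        assert not thr.values.any()
        assert table.empty

    def test_coherent_effect_yields_single_surviving_cluster(self, parallel):
        layout, cube = _cube_layout(amplitude=4.0)
        subs = _subject_copes(parallel, layout, 8)
        gz = group_one_sample(subs)
        thr, table = cluster_threshold(gz, 3.1, 0.05, subject_maps=subs, n_perm=256)
        surviving = table[table["survives"]]
        assert len(surviving) == 1
        assert thr.values[cube].max() > 3.1

    def test_permutation_null_matches_exhaustive_enumeration(self, parallel):
        layout, _ = _cube_layout()
        subs = _subject_copes(parallel, layout, 4)
        null, exhaustive = max_cluster_null(subs, z_form=2.3, n_perm=16, seed=0)
        assert exhaustive and len(null) == 16
        # independent oracle: enumerate all sign patterns by brute force
        mask = subs[0].mask
        data = np.stack([m.values[mask] for m in subs])
        from scipy import ndimage, stats as sps

        expected = []
        for signs in itertools.product((1.0, -1.0), repeat=4):
            d = np.array(signs)[:, None] * data
            mean, sd = d.mean(axis=0), d.std(axis=0, ddof=1)
            t = mean / (sd / 2.0)
            z = np.sign(t) * sps.norm.isf(sps.t.sf(np.abs(t), 3))
            supra = np.zeros(GRID, bool)
            supra[mask] = z > 2.3
            labels, n = ndimage.label(supra)
            sizes = [int((labels == i).sum()) for i in range(1, n + 1)]
            expected.append(max(sizes) if sizes else 0)
        assert sorted(null.tolist()) == sorted(expected)

    def test_null_zmaps_show_nominal_exceedance(self, parallel, noise_params):
        grid = (10, 10, 10)
        maps = []
        for s in range(10):
            run = simulate_volume_run(grid, {}, parallel, noise_params, seed=500 + s)
            maps.append(first_level_lsa(run.volume4d, parallel).copes["think"])
        z = group_one_sample(maps).masked()
        assert z.size >= 1000
        assert abs(z.mean()) < 0.1
        assert z.var() == pytest.approx(1.0, abs=0.2)
        assert (np.abs(z) > 1.96).mean() == pytest.approx(0.05, abs=0.02)

    def test_thresholded_outputs_subset_of_supra_voxels(self, parallel):
        layout, _ = _cube_layout(amplitude=4.0)
        subs = _subject_copes(parallel, layout, 8)
        gz = group_one_sample(subs)
        thr, _ = cluster_threshold(gz, 3.1, 0.05, subject_maps=subs, n_perm=256)
        surviving = thr.values != 0
        assert np.all(gz.values[surviving] > 3.1)


class TestConjunctionDisjunction:
    def _two_region_maps(self, parallel):
        # noise_sd 1.0 keeps realistic between-subject variability so the
        # sign-flip null separates cleanly from the observed clusters
        shared = np.zeros(GRID, bool)
        shared[1:3, 1:3, 1:3] = True
        unique = np.zeros(GRID, bool)
        unique[4:6, 4:6, 4:6] = True
        layout_a = {"shared": (shared, {"think": 3.0}),
                    "unique": (unique, {"think": 3.0})}
        layout_b = {"shared": (shared, {"think": 3.0})}
        subs_a = _subject_copes(parallel, layout_a, 8, noise_sd=1.0)
        subs_b = _subject_copes(parallel, layout_b, 8, noise_sd=1.0, seed0=300)
        return shared, unique, subs_a, subs_b

    def test_conjunction_with_self_is_thresholded_map(self, parallel):
        layout, _ = _cube_layout(amplitude=4.0)
        subs = _subject_copes(parallel, layout, 8)
        gz = group_one_sample(subs)
        conj, _ = conjunction(gz, gz, 2.3, 0.01, subs, subs, n_perm=256)
        thr, _ = cluster_threshold(gz, 2.3, 0.01, subject_maps=subs, n_perm=256)
        np.testing.assert_allclose(conj.values, thr.values)

    def test_min_statistic_bounded_by_both_inputs(self, parallel, rng):
        mask = np.ones(GRID, bool)
        z1 = StatMap(rng.standard_normal(GRID) + 3, mask)
        z2 = StatMap(rng.standard_normal(GRID) + 3, mask)
        conj, _ = conjunction(z1, z2, z_form=2.3, alpha=0.01)
        active = conj.values != 0
        assert np.all(conj.values[active] <= z1.values[active] + 1e-12)
        assert np.all(conj.values[active] <= z2.values[active] + 1e-12)

    def test_disjoint_activations_empty_conjunction(self, parallel):
        shared, unique, subs_a, subs_b = self._two_region_maps(parallel)
        # maps with no common activation: unique-only vs shared-only
        layout_u = {"unique": (unique, {"think": 4.0})}
        subs_u = _subject_copes(parallel, layout_u, 8, noise_sd=0.3, seed0=400)
        z_u = group_one_sample(subs_u)
        z_b = group_one_sample(subs_b)
        conj, table = conjunction(z_u, z_b, 2.3, 0.01, subs_u, subs_b, n_perm=256)
        assert not conj.values.any()

    def test_disjunction_retains_only_unique_region(self, parallel):
        shared, unique, subs_a, subs_b = self._two_region_maps(parallel)
        z_a, z_b = group_one_sample(subs_a), group_one_sample(subs_b)
        conj, _ = conjunction(z_a, z_b, 2.3, 0.01, subs_a, subs_b, n_perm=256)
        disj, _ = disjunction(z_a, conj, 3.1, 0.05, subject_maps=subs_a, n_perm=256)
        active = disj.values != 0
        assert active[unique].any()
        assert not active[shared].any()

    def test_empty_conjunction_mask_is_plain_threshold(self, parallel):
        layout, _ = _cube_layout(amplitude=4.0)
        subs = _subject_copes(parallel, layout, 8)
        gz = group_one_sample(subs)
        empty = StatMap(np.zeros(GRID), gz.mask)
        disj, _ = disjunction(gz, empty, 3.1, 0.05, subject_maps=subs, n_perm=256)
        thr, _ = cluster_threshold(gz, 3.1, 0.05, subject_maps=subs, n_perm=256)
        np.testing.assert_allclose(disj.values, thr.values)

    def test_map_inside_conjunction_mask_empties(self, parallel):
        layout, _ = _cube_layout(amplitude=4.0)
        subs = _subject_copes(parallel, layout, 8)
        gz = group_one_sample(subs)
        full = StatMap(np.where(gz.values > 0, gz.values, 1.0), gz.mask)
        disj, table = disjunction(gz, full, 3.1, 0.05)
        assert not disj.values.any()


def test_t_to_z_preserves_tail_probability():
    t = np.array([-3.0, -0.5, 0.0, 0.5, 3.0])
    z = t_to_z(t, df=9)
    from scipy import stats as sps

    np.testing.assert_allclose(sps.norm.sf(z[t > 0]), sps.t.sf(t[t > 0], 9), rtol=1e-10)
    np.testing.assert_allclose(z[t < 0], -z[t > 0][::-1], atol=1e-12)
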