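import json

import numpy as np
import pytest

from olfica.confounds import dvars, framewise_displacement
from olfica.hemodynamics import canonical_hrf
from olfica.synthetic import (
    ActivationModeration,
    CohortSpec,
    build_ground_truth,
    draw_covariates,
    generate_cohort,
    hit_probability,
    plant_spatial_maps,
    schedule_events,
    simulate_motion,
    simulate_subject_bold,
)


class TestPlantSpatialMaps:
    def test_pairwise_decorrelation_bound(self):
        maps = plant_spatial_maps((15, 15, 12), 5, seed=3)
        flat = maps.reshape(5, -1)
        flat = flat - flat.mean(axis=1, keepdims=True)
        gram = np.corrcoef(flat)
        off = np.abs(gram - np.eye(5)).max()
        assert off < 0.2

    def test_deterministic_for_fixed_seed(self):
        a = plant_spatial_maps((15, 15, 12), 3, seed=7)
        b = plant_spatial_maps((15, 15, 12), 3, seed=7)
        assert np.array_equal(a, b)

    def test_unit_peak(self):
        maps = plant_spatial_maps((15, 15, 12), 2, seed=1)
        assert np.allclose(maps.reshape(2, -1).max(axis=1), 1.0)

    def test_small_grid_rejected_naming_axis(self):
        with pytest.raises(ValueError, match="axis z"):
            plant_spatial_maps((15, 15, 8), 2, seed=1)


class TestScheduleEvents:
    def test_degenerate_accuracies(self):
        spec = CohortSpec(n_subjects=2)
        ev = schedule_events(spec, 1.0, seed=0)
        stim = ev[ev.trial_type == "stim"]
        assert len(stim) == 32
        assert (stim.outcome == "hit").all()
        ev0 = schedule_events(spec, 0.0, seed=0)
        assert (ev0[ev0.trial_type == "stim"].outcome == "miss").all()

    def test_blocks_and_baselines(self):
        spec = CohortSpec(n_subjects=2)
        ev = schedule_events(spec, 0.5, seed=4)
        assert (ev[ev.trial_type == "baseline"].shape[0]) == 4
        assert ev.onset.is_monotonic_increasing
        assert (ev.duration == 16.0).all()
        # every odorant appears exactly 4 times
        stim = ev[ev.trial_type == "stim"]
        assert stim.odorant.value_counts().eq(4).all()

    def test_hit_count_matches_replayed_bernoulli_stream(self):
        spec = CohortSpec(n_subjects=2)
        ev = schedule_events(spec, 0.5, seed=11)
        # replay the RNG stream with the same consumption pattern
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(spec.reps_per_run):
            rng.permutation(spec.odorants)
            for _ in range(spec.odorants):
                if rng.random() < 0.5:
                    hits += 1
        assert (ev[ev.trial_type == "stim"].outcome == "hit").sum() == hits

    def test_insufficient_run_length_reports_required_frames(self):
        with pytest.raises(ValueError, match="288"):
            CohortSpec(n_subjects=2, n_frames=100)


class TestSimulateMotion:
    def test_bounded_steps_without_spikes(self):
        motion = simulate_motion(100, spike_prob=0.0, seed=5)
        assert np.abs(np.diff(motion[:, :3], axis=0)).max() < 1.0
        assert framewise_displacement(motion).max() < 1.0

    def test_forced_spike_exceeds_fd_threshold(self):
        motion = simulate_motion(100, spike_prob=1.0, seed=5)
        assert (framewise_displacement(motion) > 1.0).any()

    def test_spike_rate_matches_binomial_expectation(self):
        count = 0
        n_seeds = 30
        for seed in range(n_seeds):
            fd = framewise_displacement(simulate_motion(200, 0.05, seed))
            count += (fd > 1.0).sum()
        mean_rate = count / n_seeds
        # expectation 199 * 0.05 ~ 10 spikes; allow 4 binomial sigma
        sigma = np.sqrt(199 * 0.05 * 0.95 / n_seeds)
        assert abs(mean_rate - 199 * 0.05) < 4 * sigma + 1


class TestSimulateSubjectBold:
    def _noiseless_spec(self, **kw):
        defaults = dict(
            n_subjects=3, reps_per_run=2, thermal_sd=0.0, drift_amplitude=0.5,
            intrinsic_sd=0.0, tmfc_gain=0.0, n_components=5, n_task_components=0,
            moderated_component=0,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_zero_amplitudes_zero_noise_equals_drift_field(self):
        spec = self._noiseless_spec()
        cov = draw_covariates(spec, 1)
        mod = ActivationModeration(0, 0, 0, 0, 0, 0, 0)
        gt = build_ground_truth(spec, cov, seed=2, moderation=mod)
        ev = schedule_events(spec, 0.5, seed=3)
        motion = simulate_motion(spec.n_frames, 0.0, seed=4)
        bold, _ = simulate_subject_bold(spec, gt, ev, motion, 0, seed=5)
        sig = bold.data[gt.analysis_mask]  # voxels x t
        ramp = np.linspace(-1.0, 1.0, spec.n_frames)
        # every in-mask voxel is an exact linear ramp (the drift field)
        for v in range(0, sig.shape[0], 251):
            slope = np.polyfit(ramp, sig[v], 1)[0]
            assert np.allclose(sig[v], slope * ramp, atol=1e-10)

    def test_single_component_regression_returns_map_value(self):
        spec = self._noiseless_spec(
            n_task_components=1, base_hit_amplitudes=(1.0,), drift_amplitude=0.0,
            intrinsic_sd=1.0,
        )
        cov = draw_covariates(spec, 1)
        mod = ActivationModeration(0, 0, 0, 0, 0, 0, 0)
        gt = build_ground_truth(spec, cov, seed=2, moderation=mod)
        # silence all but component 0
        gt.planted_task_amplitudes[:, 1:, :] = 0.0
        gt.planted_maps_z[1:] = 0.0
        ev = schedule_events(spec, 0.7, seed=3)
        motion = simulate_motion(spec.n_frames, 0.0, seed=4)
        bold, tcs = simulate_subject_bold(spec, gt, ev, motion, 0, seed=5)
        tc0 = tcs[:, 0]
        sig = bold.data[gt.analysis_mask]
        slopes = np.linalg.lstsq(
            np.column_stack([tc0, np.ones_like(tc0)]), sig.T, rcond=None
        )[0][0]
        expected = gt.planted_maps_z[0][gt.analysis_mask]
        # components 1..4 still carry intrinsic signal; but maps were zeroed
        assert np.allclose(slopes, expected, atol=1e-8)

    def test_noiseless_contribution_linear_in_amplitude(self):
        spec = self._noiseless_spec(
            n_task_components=1, base_hit_amplitudes=(1.0,), drift_amplitude=0.0,
        )
        cov = draw_covariates(spec, 1)
        mod = ActivationModeration(0, 0, 0, 0, 0, 0, 0)
        gt = build_ground_truth(spec, cov, seed=2, moderation=mod)
        ev = schedule_events(spec, 0.7, seed=3)
        motion = simulate_motion(spec.n_frames, 0.0, seed=4)
        b1, _ = simulate_subject_bold(spec, gt, ev, motion, 0, seed=5)
        gt.planted_task_amplitudes *= 2.0
        b2, _ = simulate_subject_bold(spec, gt, ev, motion, 0, seed=5)
        m = gt.analysis_mask
        assert np.allclose(b2.data[m], 2.0 * b1.data[m], atol=1e-10)

    def test_grid_mismatch_rejected(self):
        spec = self._noiseless_spec()
        cov = draw_covariates(spec, 1)
        gt = build_ground_truth(spec, cov, seed=2)
        other = CohortSpec(n_subjects=3, grid=(16, 15, 12), reps_per_run=2)
        ev = schedule_events(spec, 0.5, seed=3)
        motion = simulate_motion(spec.n_frames, 0.0, seed=4)
        with pytest.raises(ValueError, match="grid"):
            simulate_subject_bold(other, gt, ev, motion, 0, seed=5)


class TestCohortBundle:
    def test_regenerating_is_byte_identical_on_disk(self, tmp_path):
        spec = CohortSpec(n_subjects=2, reps_per_run=2, n_components=3,
                          n_task_components=2, base_hit_amplitudes=(1.0, 0.8),
                          moderated_component=1, tmfc_seed_component=0)
        generate_cohort(spec, seed=9, out_dir=tmp_path / "a")
        generate_cohort(spec, seed=9, out_dir=tmp_path / "b")
        for rel in ["sub-01/func/sub-01_run-1_bold.nii.gz", "participants.tsv",
                    "ground_truth.json"]:
            a = (tmp_path / "a" / rel).read_bytes()
            b = (tmp_path / "b" / rel).read_bytes()
            assert a == b, rel

    def test_manifest_records_one_seed_per_subject(self, tmp_path):
        spec = CohortSpec(n_subjects=3, reps_per_run=2, n_components=3,
                          n_task_components=2, base_hit_amplitudes=(1.0, 0.8),
                          moderated_component=1)
        generate_cohort(spec, seed=12, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "ground_truth.json").read_text())
        sub_seeds = [k for k in manifest["seeds"] if k.startswith("sub-")]
        assert len(sub_seeds) == 3

    def test_carrier_count_matches_replayed_draws(self):
        spec = CohortSpec(n_subjects=16, apoe_fraction=0.5)
        cov = draw_covariates(spec, seed=77)
        rng = np.random.default_rng(77)
        expected = (rng.random(16) < 0.5).sum()
        assert cov["apoe4"].sum() == expected

    def test_hit_probability_increases_with_sdoit(self):
        spec = CohortSpec(n_subjects=2)
        p = hit_probability(spec, np.array([0, 4, 8]))
        assert p[0] < p[1] < p[2]

    def test_planted_motion_spikes_flagged_by_fd_dvars(self):
        # task-quiet cohort: the only intensity jumps are the planted motion
        # artifacts, so FD/DVARS flag the spike frames (and, for DVARS, the
        # frame after each spike, where the offset returns to baseline)
        spec = CohortSpec(
            n_subjects=1, reps_per_run=2, spike_prob=0.03,
            n_components=3, n_task_components=0, intrinsic_sd=0.2,
            base_hit_amplitudes=(), moderated_component=0,
        )
        coh = generate_cohort(spec, seed=31)
        found_spike = False
        for r in range(2):
            motion = coh.motion[0][r]
            fd = framewise_displacement(motion)
            planted = set(int(f) for f in np.flatnonzero(fd > 1.0))
            dv = dvars(coh.bold[0][r])
            flagged = set(int(f) for f in np.flatnonzero((fd > 1.0) | (dv > 2.0)))
            expected = planted | {f + 1 for f in planted if f + 1 < len(fd)}
            assert flagged == expected
            found_spike = found_spike or bool(planted)
        assert found_spike
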