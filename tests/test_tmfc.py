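import numpy as np
import pandas as pd
import pytest

from olfica.confounds import build_confound_matrix
from olfica.hemodynamics import build_task_design, canonical_hrf
from olfica.io import Bold4D
from olfica.tmfc import build_ppi_design, extract_tmfc, fit_voxelwise_glm


@pytest.fixture(scope="module")
def run_fixture():
    """Two runs of events/motion/bold for one synthetic subject."""
    rng = np.random.default_rng(30)
    hrf = canonical_hrf(10.0, 2.0)
    n = 100
    designs, cms, bolds = [], [], []
    noise_mask = np.zeros((8, 8, 6), bool)
    noise_mask[:2, :2, :2] = True
    mask = ~noise_mask
    for r in range(2):
        ev = pd.DataFrame(
            {
                "onset": np.arange(6) * 32.0,
                "duration": 16.0,
                "trial_type": "stim",
                "odorant": np.arange(6) % 8,
                "outcome": ["hit", "miss"] * 3,
            }
        )
        designs.append(build_task_design(ev, 2.0, n, hrf).frame)
        motion = np.cumsum(rng.normal(0, 0.01, (n, 6)), axis=0)
        data = rng.standard_normal((8, 8, 6, n))
        bold = Bold4D(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr_s=2.0, mask=mask)
        cms.append(build_confound_matrix(bold, motion, noise_mask))
        bolds.append(bold)
    seed_tc = rng.standard_normal(2 * n) + np.concatenate(
        [d["hit"].to_numpy() for d in designs]
    )
    return designs, cms, bolds, seed_tc, mask


class TestBuildPpiDesign:
    def test_column_bookkeeping(self, run_fixture):
        designs, cms, _, seed_tc, _ = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        cols = design.columns
        assert sum(c.startswith("intercept_run") for c in cols) == 2
        assert {"hit", "miss", "seed", "hit_x_seed", "miss_x_seed"} <= set(cols)
        n_spikes = sum("motion_outlier" in c for c in cols)
        n_dct = sum(c.startswith("cosine") for c in cols)
        n_motion = sum(
            c.split("_run")[0].startswith(("trans", "rot")) for c in cols
        )
        assert n_motion == 24
        assert sum(c.startswith("a_comp_cor") for c in cols) == 5
        expected = 2 + 2 + 1 + 2 + 24 + 5 + n_spikes + n_dct
        assert len(cols) == expected

    def test_interaction_is_product_of_centered_parents(self, run_fixture):
        designs, cms, _, seed_tc, _ = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        f = design.frame
        n = len(designs[0])
        for r in range(2):
            sl = slice(r * n, (r + 1) * n)
            seed_run = seed_tc[sl] - seed_tc[sl].mean()
            hit_run = designs[r]["hit"].to_numpy()
            hit_c = hit_run - hit_run.mean()
            assert np.allclose(f["hit_x_seed"][sl], seed_run * hit_c, atol=1e-12)

    def test_constant_seed_drops_interactions(self, run_fixture):
        designs, cms, _, _, _ = run_fixture
        n = 2 * len(designs[0])
        design = build_ppi_design(np.full(n, 3.0), designs, cms)
        assert "hit_x_seed" in design.dropped_columns
        assert "seed" in design.dropped_columns

    def test_seed_offset_invariance_of_interaction_betas(self, run_fixture):
        designs, cms, bolds, seed_tc, _ = run_fixture
        concat = Bold4D(
            data=np.concatenate([b.data for b in bolds], axis=3),
            affine=bolds[0].affine, tr_s=2.0, mask=bolds[0].mask,
        )
        d1 = build_ppi_design(seed_tc, designs, cms)
        d2 = build_ppi_design(seed_tc + 42.0, designs, cms)
        f1 = extract_tmfc(fit_voxelwise_glm(concat, d1))
        f2 = extract_tmfc(fit_voxelwise_glm(concat, d2))
        assert np.allclose(f1.hit, f2.hit, atol=1e-9)

    def test_length_mismatch_rejected(self, run_fixture):
        designs, cms, _, _, _ = run_fixture
        with pytest.raises(ValueError, match="length"):
            build_ppi_design(np.zeros(17), designs, cms)


class TestFitVoxelwiseGlm:
    def test_exact_linear_combination_recovered(self, run_fixture):
        designs, cms, bolds, seed_tc, mask = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        x = design.matrix
        rng = np.random.default_rng(31)
        coefs = rng.standard_normal((x.shape[1], 5))
        data = np.zeros((8, 8, 6, x.shape[0]))
        vox = [(3, 3, 3), (4, 4, 4), (5, 2, 1), (2, 5, 3), (6, 6, 5)]
        for j, v in enumerate(vox):
            data[v] = x @ coefs[:, j]
        bold = Bold4D(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr_s=2.0, mask=mask)
        fit = fit_voxelwise_glm(bold, design)
        mask_idx = {tuple(t): i for i, t in enumerate(np.argwhere(mask))}
        for j, v in enumerate(vox):
            for k, name in enumerate(design.columns):
                assert fit.betas[name][mask_idx[v]] == pytest.approx(
                    coefs[k, j], abs=1e-8
                )

    def test_matches_normal_equations_oracle_per_voxel(self, run_fixture):
        designs, cms, bolds, seed_tc, _ = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        x = design.matrix
        rng = np.random.default_rng(32)
        small_mask = np.zeros((5, 1, 1), bool)
        small_mask[:, 0, 0] = True
        data = rng.standard_normal((5, 1, 1, x.shape[0]))
        bold = Bold4D(data=data, affine=np.eye(4), tr_s=2.0, mask=small_mask)
        fit = fit_voxelwise_glm(bold, design)
        for v in range(5):
            y = data[v, 0, 0]
            oracle = np.linalg.solve(x.T @ x, x.T @ y)
            got = np.array([fit.betas[c][v] for c in design.columns])
            assert np.allclose(got, oracle, atol=1e-8)

    def test_voxel_permutation_equivariance(self, run_fixture):
        designs, cms, bolds, seed_tc, mask = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        concat = np.concatenate([b.data for b in bolds], axis=3)
        bold = Bold4D(data=concat, affine=bolds[0].affine, tr_s=2.0, mask=mask)
        fit = fit_voxelwise_glm(bold, design)
        # permute along x-axis: flip the volume
        flipped = Bold4D(
            data=concat[::-1], affine=bolds[0].affine, tr_s=2.0, mask=mask[::-1]
        )
        fit_f = fit_voxelwise_glm(flipped, design)
        a = np.zeros(mask.shape)
        a[mask] = fit.betas["hit_x_seed"]
        b = np.zeros(mask.shape)
        b[mask[::-1]] = fit_f.betas["hit_x_seed"]
        assert np.allclose(a, b[::-1], atol=1e-12)

    def test_nuisance_projection_invariance(self, run_fixture):
        designs, cms, bolds, seed_tc, mask = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        concat = np.concatenate([b.data for b in bolds], axis=3)
        bold = Bold4D(data=concat, affine=bolds[0].affine, tr_s=2.0, mask=mask)
        base = extract_tmfc(fit_voxelwise_glm(bold, design))
        # add a combination of nuisance columns to every voxel
        nuis = design.frame["a_comp_cor_00"].to_numpy() * 5.0 + design.frame[
            "trans_x"
        ].to_numpy() * 2.0
        shifted = Bold4D(
            data=concat + nuis[None, None, None, :], affine=bolds[0].affine,
            tr_s=2.0, mask=mask,
        )
        pert = extract_tmfc(fit_voxelwise_glm(shifted, design))
        assert np.allclose(base.hit, pert.hit, atol=1e-8)
        assert np.allclose(base.miss, pert.miss, atol=1e-8)


class TestPlantedCouplingRecovery:
    def test_zero_noise_gain_recovered_exactly(self, run_fixture):
        # data built from the design columns plus a known interaction gain:
        # with no noise the interaction beta equals the planted gain to 1e-6
        designs, cms, _, seed_tc, mask = run_fixture
        design = build_ppi_design(seed_tc, designs, cms)
        f = design.frame
        g = 0.7
        base = (
            1.3 * f["seed"].to_numpy()
            + 0.5 * f["hit"].to_numpy()
            - 0.2 * f["miss"].to_numpy()
        )
        data = np.zeros((8, 8, 6, len(f)))
        data[mask] = base
        targets = np.zeros(mask.shape, bool)
        targets[4:6, 4:6, 2:4] = True
        targets &= mask
        data[targets] += g * f["hit_x_seed"].to_numpy()
        bold = Bold4D(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr_s=2.0, mask=mask)
        maps = extract_tmfc(fit_voxelwise_glm(bold, design))
        tsel = targets[mask]
        assert np.abs(maps.hit[tsel] - g).max() < 1e-6
        assert np.abs(maps.hit[~tsel]).max() < 1e-6
        assert np.abs(maps.miss).max() < 1e-6

    def test_subject_without_misses_flagged(self):
        hrf = canonical_hrf(10.0, 2.0)
        n = 80
        rng = np.random.default_rng(33)
        ev = pd.DataFrame(
            {
                "onset": np.arange(4) * 32.0,
                "duration": 16.0,
                "trial_type": "stim",
                "odorant": np.arange(4),
                "outcome": "hit",
            }
        )
        design_t = build_task_design(ev, 2.0, n, hrf).frame
        noise_mask = np.zeros((8, 8, 6), bool)
        noise_mask[:2, :2, :2] = True
        mask = ~noise_mask
        bold = Bold4D(
            data=rng.standard_normal((8, 8, 6, n)),
            affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr_s=2.0, mask=mask,
        )
        cm = build_confound_matrix(bold, np.zeros((n, 6)), noise_mask)
        seed_tc = rng.standard_normal(n)
        design = build_ppi_design(seed_tc, [design_t], [cm])
        maps = extract_tmfc(fit_voxelwise_glm(bold, design))
        assert maps.miss is None
        assert maps.hit is not None
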