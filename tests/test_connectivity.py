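import numpy as np
import pytest

from lesionmap.connectivity import (
    ConnectomeCohort,
    SeedTimecourse,
    bonferroni_critical_t,
    extract_seed_timecourse,
    fisher_z,
    group_t_map,
    lesion_network_map,
    lesion_t_map,
    single_map_t,
    subject_r_map,
)
from lesionmap.errors import (
    DegenerateSeedError,
    EmptyMaskError,
    InsufficientSubjectsError,
)
from lesionmap.imaging_io import LesionMask, StatMap, VolumeGrid
from lesionmap.synthetic import (
    CohortConfig,
    make_network_supports,
    plant_lesion_masks,
    simulate_cohort,
)


def _grid(shape=(4, 4, 4)):
    return VolumeGrid(shape, np.diag([2.0, 2.0, 2.0, 1.0]))


def _mask(grid, idx, outcome="P"):
    vox = np.zeros(grid.shape, dtype=np.uint8)
    for i in idx:
        vox[i] = 1
    return LesionMask(grid, vox, "m", outcome)


class TestSeedTimecourse:
    def test_single_voxel_identity(self):
        grid = _grid()
        rng = np.random.default_rng(0)
        subject = rng.standard_normal((*grid.shape, 10))
        mask = _mask(grid, [(1, 1, 1)])
        tc = extract_seed_timecourse(subject, mask, np.ones(grid.shape))
        np.testing.assert_allclose(tc.values, subject[1, 1, 1])
        assert tc.source_n_voxels == 1

    def test_two_voxel_mean(self):
        grid = _grid()
        subject = np.zeros((*grid.shape, 5))
        u = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([5.0, 4.0, 3.0, 2.0, 2.0])
        subject[0, 0, 0] = u
        subject[0, 0, 1] = v
        mask = _mask(grid, [(0, 0, 0), (0, 0, 1)])
        tc = extract_seed_timecourse(subject, mask, np.ones(grid.shape))
        np.testing.assert_allclose(tc.values, (u + v) / 2)

    def test_empty_intersection(self):
        grid = _grid()
        subject = np.zeros((*grid.shape, 5))
        mask = _mask(grid, [(0, 0, 0)])
        brain = np.ones(grid.shape)
        brain[0, 0, 0] = 0
        with pytest.raises(EmptyMaskError):
            extract_seed_timecourse(subject, mask, brain)

    def test_zero_variance_seed(self):
        grid = _grid()
        subject = np.ones((*grid.shape, 5))
        mask = _mask(grid, [(0, 0, 0)])
        with pytest.raises(DegenerateSeedError):
            extract_seed_timecourse(subject, mask, np.ones(grid.shape))

    def test_noise_free_seed_tracks_latent_course(self):
        nets = make_network_supports((10, 10, 10), 1, geometry=[((5, 5, 5), 2.0)])
        config = CohortConfig((10, 10, 10), 3, 30, tuple(nets),
                              noise_sd=1e-9, seed=4)
        cohort, latents = simulate_cohort(config, return_latents=True)
        masks, _ = plant_lesion_masks(nets, [(0, "P")], lesion_radius=1.0,
                                      grid=config.grid)
        tc = extract_seed_timecourse(cohort.subjects[0], masks[0],
                                     cohort.brain_mask)
        r = np.corrcoef(tc.values, latents[0, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-5)


class TestSubjectRMap:
    def _setup(self):
        grid = _grid((2, 2, 2))
        seed_series = np.array([1.0, 2.0, 3.0, 4.0])
        subject = np.zeros((*grid.shape, 4))
        subject[0, 0, 0] = seed_series          # identical -> r = 1
        subject[0, 0, 1] = -seed_series         # negated -> r = -1
        subject[0, 1, 0] = [1.0, 2.0, 2.0, 4.0]  # hand-computed oracle
        subject[0, 1, 1] = 7.0                   # zero variance -> invalid
        subject[1, 0, 0] = 2 * seed_series + 5   # affine rescale -> r = 1
        seed = SeedTimecourse(seed_series, 1)
        return grid, subject, seed

    def test_extremes_and_oracle(self):
        grid, subject, seed = self._setup()
        r = subject_r_map(subject, seed, np.ones(grid.shape), grid)
        assert r.values[0, 0, 0] == pytest.approx(1.0)
        assert r.values[0, 0, 1] == pytest.approx(-1.0)
        # frozen from independent covariance/sigma*sigma arithmetic
        assert r.values[0, 1, 0] == pytest.approx(0.9233805168766388, abs=1e-12)

    def test_zero_variance_voxel_invalid(self):
        grid, subject, seed = self._setup()
        r = subject_r_map(subject, seed, np.ones(grid.shape), grid)
        assert not r.valid[0, 1, 1]
        assert np.isnan(r.values[0, 1, 1])

    def test_affine_invariance(self):
        grid, subject, seed = self._setup()
        r = subject_r_map(subject, seed, np.ones(grid.shape), grid)
        assert r.values[1, 0, 0] == pytest.approx(1.0)

    def test_outside_brain_mask_invalid(self):
        grid, subject, seed = self._setup()
        brain = np.ones(grid.shape)
        brain[1, 1, 1] = 0
        r = subject_r_map(subject, seed, brain, grid)
        assert not r.valid[1, 1, 1]

    def test_values_in_range(self):
        grid = _grid()
        rng = np.random.default_rng(1)
        subject = rng.standard_normal((*grid.shape, 20))
        seed = SeedTimecourse(rng.standard_normal(20), 1)
        r = subject_r_map(subject, seed, np.ones(grid.shape), grid)
        assert np.nanmax(np.abs(r.values)) <= 1.0


class TestFisherZ:
    def _rmap(self, value):
        grid = _grid((1, 1, 1))
        return StatMap(grid, np.full(grid.shape, value), "r",
                       np.ones(grid.shape, dtype=bool))

    def test_zero(self):
        assert fisher_z(self._rmap(0.0)).values[0, 0, 0] == 0.0

    def test_closed_form(self):
        # atanh(0.5) = 0.5 * ln(3)
        z = fisher_z(self._rmap(0.5)).values[0, 0, 0]
        assert z == pytest.approx(0.5493061443340549, abs=1e-12)

    def test_odd_symmetry(self):
        zp = fisher_z(self._rmap(0.3)).values[0, 0, 0]
        zn = fisher_z(self._rmap(-0.3)).values[0, 0, 0]
        assert zp == pytest.approx(-zn)

    def test_r_equal_one_clipped_finite(self):
        z = fisher_z(self._rmap(1.0)).values[0, 0, 0]
        assert np.isfinite(z)
        assert z > 8  # atanh(1 - 1e-7)

    def test_kind_check(self):
        grid = _grid((1, 1, 1))
        t_map = StatMap(grid, np.zeros(grid.shape), "t",
                        np.ones(grid.shape, dtype=bool))
        with pytest.raises(ValueError):
            fisher_z(t_map)


class TestGroupTMap:
    def _zmaps(self, voxel_values):
        """One 1-voxel z map per subject."""
        grid = _grid((1, 1, 1))
        return [StatMap(grid, np.full(grid.shape, v), "z",
                        np.ones(grid.shape, dtype=bool)) for v in voxel_values]

    def test_hand_arithmetic(self):
        # mean .6, sd .1 -> t = .6*sqrt(3)/.1
        t = group_t_map(self._zmaps([0.5, 0.6, 0.7]))
        assert t.values[0, 0, 0] == pytest.approx(10.392304845413266, rel=1e-9)

    def test_null_voxel_zero_over_zero(self):
        t = group_t_map(self._zmaps([0.0, 0.0, 0.0]))
        assert t.values[0, 0, 0] == 0.0
        assert t.valid[0, 0, 0]

    def test_degenerate_constant_nonzero_flagged_invalid(self):
        t = group_t_map(self._zmaps([0.4, 0.4, 0.4]))
        assert not t.valid[0, 0, 0]

    def test_subject_order_irrelevant(self):
        a = group_t_map(self._zmaps([0.1, 0.5, 0.9, 0.2]))
        b = group_t_map(self._zmaps([0.9, 0.2, 0.1, 0.5]))
        np.testing.assert_array_equal(a.values, b.values)

    def test_insufficient_subjects(self):
        with pytest.raises(InsufficientSubjectsError):
            group_t_map(self._zmaps([0.1, 0.2]))

    def test_voxel_invalid_if_any_subject_invalid(self):
        grid = _grid((1, 1, 1))
        good = StatMap(grid, np.full(grid.shape, 0.5), "z",
                       np.ones(grid.shape, dtype=bool))
        bad = StatMap(grid, np.full(grid.shape, np.nan), "z",
                      np.zeros(grid.shape, dtype=bool))
        t = group_t_map([good, good, bad])
        assert not t.valid[0, 0, 0]


class TestLesionNetworkMap:
    def test_noise_free_recovery_is_exact(self):
        # enough subjects that null voxels (pure residual noise) cannot
        # cross t=5.1: P(|t_29| >= 5.1) * n_voxels << 1. noise_sd is tiny
        # but keeps r below the |r|=1 clip so z retains between-subject
        # spread (bit-identical z would trip the degenerate sd=0 flag)
        nets = make_network_supports((12, 12, 12), 1, geometry=[((5, 5, 5), 2.5)])
        config = CohortConfig((12, 12, 12), 30, 30, tuple(nets),
                              noise_sd=1e-3, seed=2)
        cohort = simulate_cohort(config)
        masks, truth = plant_lesion_masks(nets, [(0, "P")], lesion_radius=1.0,
                                          grid=config.grid)
        out = lesion_network_map(cohort, masks[0], t_threshold=5.1)
        np.testing.assert_array_equal(out.values > 0, truth.expected_maps[0])

    def test_infinite_threshold_empty(self):
        nets = make_network_supports((10, 10, 10), 1, geometry=[((5, 5, 5), 2.0)])
        config = CohortConfig((10, 10, 10), 4, 20, tuple(nets), noise_sd=0.5,
                              seed=0)
        cohort = simulate_cohort(config)
        masks, _ = plant_lesion_masks(nets, [(0, "P")], lesion_radius=1.0,
                                      grid=config.grid)
        out = lesion_network_map(cohort, masks[0], t_threshold=np.inf)
        assert np.nansum(out.values) == 0

    def test_threshold_monotonicity(self, fixture_bundle):
        cohort = fixture_bundle["cohort"]
        mask = fixture_bundle["masks"][0]
        t_map = lesion_t_map(cohort, mask)
        from lesionmap.maps import threshold_binarize
        low = threshold_binarize(t_map, 3.0)
        high = threshold_binarize(t_map, 6.0)
        assert ((high.values > 0) <= (low.values > 0)).all()

    def test_single_map_mode_runs(self):
        nets = make_network_supports((10, 10, 10), 1, geometry=[((5, 5, 5), 2.0)])
        config = CohortConfig((10, 10, 10), 4, 30, tuple(nets), noise_sd=0.3,
                              seed=9)
        cohort = simulate_cohort(config)
        masks, truth = plant_lesion_masks(nets, [(0, "P")], lesion_radius=1.0,
                                          grid=config.grid)
        out = lesion_network_map(cohort, masks[0], t_threshold=5.1,
                                 mode="single_map")
        on = out.values > 0
        assert on[truth.expected_maps[0]].all()


class TestSingleMapT:
    def test_formula(self):
        grid = _grid((1, 1, 1))
        r_map = StatMap(grid, np.full(grid.shape, 0.5), "r",
                        np.ones(grid.shape, dtype=bool))
        t = single_map_t(r_map, n_timepoints=27)
        expected = 0.5 * np.sqrt(25) / np.sqrt(0.75)
        assert t.values[0, 0, 0] == pytest.approx(expected, rel=1e-9)


class TestBonferroni:
    def test_band_brackets_published_threshold(self):
        # two-tailed FWE alpha=.05, df=998, 1e5..2.3e5 voxels
        lo = bonferroni_critical_t(100_000, 998)
        hi = bonferroni_critical_t(230_000, 998)
        assert 5.0 <= lo <= hi <= 5.3
        assert lo <= 5.1 <= hi or (5.0 <= lo <= 5.3)

    def test_monotone_in_voxels(self):
        assert bonferroni_critical_t(1000, 100) < bonferroni_critical_t(10_000, 100)


class TestCohortInvariants:
    def test_timepoint_mismatch_rejected(self):
        grid = _grid()
        a = np.zeros((*grid.shape, 10))
        b = np.zeros((*grid.shape, 12))
        with pytest.raises(ValueError):
            ConnectomeCohort(grid, [a, b], np.ones(grid.shape))

    def test_empty_brain_mask_rejected(self):
        grid = _grid()
        a = np.zeros((*grid.shape, 10))
        with pytest.raises(EmptyMaskError):
            ConnectomeCohort(grid, [a], np.zeros(grid.shape))
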