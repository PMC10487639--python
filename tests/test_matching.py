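import numpy as np
import pytest

import tomomatch as tm
from tomomatch.geometry import (
    euler_to_matrix,
    geodesic_distance,
    generate_orientation_set,
    quaternions_from_matrices,
)
from tomomatch.matching import _wedge_filter_box, score_at_positions

WEDGE = tm.WedgeSpec(39.0, 39.0)


def _brute_force_lcc(volume, template_wedged, mask, position):
    """Direct-space evaluation of the masked local correlation at one voxel."""
    m = mask.data
    p = m.sum()
    b = m.shape[0]
    c = b // 2
    t_mean = (m * template_wedged).sum() / p
    sigma_t = np.sqrt((m * (template_wedged - t_mean) ** 2).sum() / p)
    x, y, z = position
    patch = volume.data[x - c : x - c + b, y - c : y - c + b, z - c : z - c + b]
    m1 = (m * patch).sum() / p
    m2 = (m * patch * patch).sum() / p
    sigma_v = np.sqrt(m2 - m1 * m1)
    return (m * (template_wedged - t_mean) * patch).sum() / (p * sigma_t * sigma_v)


class TestRotateVolume:
    def test_identity_rotation_round_trip(self, blob_template):
        out = tm.rotate_volume(blob_template, tm.EulerTriplet(0, 0, 0))
        np.testing.assert_allclose(out.data, blob_template.data, atol=1e-6)

    def test_delta_maps_to_rotated_coordinate(self):
        n = 17
        data = np.zeros((n, n, n))
        src = (12, 8, 8)
        data[src] = 1.0
        vol = tm.DensityVolume(data, 10.0)
        out = tm.rotate_volume(vol, tm.EulerTriplet(90.0, 0.0, 0.0), interpolation="linear")
        # oracle: rotate the coordinate by hand about center floor(n/2)
        c = np.array([n // 2] * 3)
        r = euler_to_matrix(tm.EulerTriplet(90.0, 0.0, 0.0))
        target = np.rint(r @ (np.array(src) - c) + c).astype(int)
        assert out.data[tuple(target)] == pytest.approx(1.0, abs=1e-6)

    def test_smooth_blob_intensity_preserved(self):
        n = 32
        grid = np.arange(n) - n // 2
        x, y, z = np.meshgrid(grid, grid, grid, indexing="ij")
        blob = np.exp(-0.5 * ((x - 2) ** 2 + (y + 1) ** 2 + z**2) / 3.0**2)
        vol = tm.DensityVolume(blob, 10.0)
        out = tm.rotate_volume(vol, tm.EulerTriplet(33.0, 57.0, -110.0))
        assert out.data.sum() == pytest.approx(blob.sum(), rel=0.01)

    def test_non_cubic_rejected(self):
        with pytest.raises(ValueError):
            tm.rotate_volume(tm.DensityVolume(np.zeros((8, 8, 10)), 1.0), tm.EulerTriplet(0, 0, 0))

    def test_unknown_interpolation_rejected(self, blob_template):
        with pytest.raises(ValueError):
            tm.rotate_volume(blob_template, tm.EulerTriplet(0, 0, 0), interpolation="sinc")


class TestLocalStd:
    def test_constant_volume_gives_zero(self, blob_mask):
        vol = tm.DensityVolume(np.full((32, 32, 32), 7.0), 14.0)
        out = tm.local_std(vol, blob_mask)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        vol = tm.DensityVolume(rng.normal(size=(16, 16, 16)), 10.0)
        mask = tm.build_spherical_mask(8, 50.0, 10.0, soft_edge_sigma=1.0)
        out = tm.local_std(vol, mask)
        m, p, b, c = mask.data, mask.sum_p, 8, 4
        for x, y, z in rng.integers(4, 12, size=(10, 3)):
            patch = vol.data[x - c : x - c + b, y - c : y - c + b, z - c : z - c + b]
            m1 = (m * patch).sum() / p
            m2 = (m * patch * patch).sum() / p
            expected = np.sqrt(max(0.0, m2 - m1 * m1))
            assert out.data[x, y, z] == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 20, 20))
        mask = tm.build_spherical_mask(8, 50.0, 10.0, 1.0)
        a = tm.local_std(tm.DensityVolume(data, 10.0), mask)
        b = tm.local_std(tm.DensityVolume(data + 11.5, 10.0), mask)
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)

    def test_zero_mask_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            tm.MaskVolume(tm.DensityVolume(np.zeros((8, 8, 8)), 10.0), 0.0, 0.0)

    def test_mask_larger_than_volume_rejected(self, blob_mask):
        vol = tm.DensityVolume(np.zeros((8, 8, 8)) + 1.0, 14.0)
        with pytest.raises(ValueError):
            tm.local_std(vol, blob_mask)


class TestLccSingleOrientation:
    def test_perfect_match_scores_one(self, blob_template, blob_mask):
        tw = _wedge_filter_box(blob_template.data, WEDGE)
        vol = np.zeros((48, 48, 48))
        vol[16:32, 16:32, 16:32] = tw
        scored = tm.lcc_single_orientation(
            tm.DensityVolume(vol, 14.0), blob_template, blob_mask, WEDGE
        )
        assert scored.data[24, 24, 24] == pytest.approx(1.0, abs=1e-3)

    def test_negated_match_scores_minus_one(self, blob_template, blob_mask):
        tw = _wedge_filter_box(blob_template.data, WEDGE)
        vol = np.zeros((48, 48, 48))
        vol[16:32, 16:32, 16:32] = -tw
        scored = tm.lcc_single_orientation(
            tm.DensityVolume(vol, 14.0), blob_template, blob_mask, WEDGE
        )
        assert scored.data[24, 24, 24] == pytest.approx(-1.0, abs=1e-3)

    def test_fft_equals_direct_space_oracle(self):
        rng = np.random.default_rng(1)
        vol = tm.DensityVolume(rng.normal(size=(24, 24, 24)), 10.0)
        template = tm.make_blob_template(8, 10.0, seed=2, n_lumps=5)
        mask = tm.build_spherical_mask(8, 50.0, 10.0, 1.0)
        wedge = tm.WedgeSpec(30.0, 30.0)
        scored = tm.lcc_single_orientation(vol, template, mask, wedge)
        tw = _wedge_filter_box(template.data, wedge)
        for pos in rng.integers(4, 19, size=(5, 3)):
            expected = _brute_force_lcc(vol, tw, mask, tuple(pos))
            assert scored.data[tuple(pos)] == pytest.approx(expected, abs=1e-5)

    def test_degenerate_template_rejected(self, blob_mask):
        rng = np.random.default_rng(2)
        vol = tm.DensityVolume(rng.normal(size=(32, 32, 32)), 14.0)
        flat = tm.DensityVolume(np.ones((16, 16, 16)), 14.0)
        with pytest.raises(ValueError, match="degenerate"):
            tm.lcc_single_orientation(vol, flat, blob_mask, None)


@pytest.fixture(scope="module")
def tiny_job(blob_template, blob_mask, small_phantom):
    phantom, _ = small_phantom
    return tm.MatchJob(
        tomogram=phantom,
        template=blob_template,
        mask=blob_mask,
        orientations=generate_orientation_set(40.0),
        wedge=WEDGE,
    )


class TestRunMatch:
    def test_single_orientation_reduces_to_lcc(self, blob_template, blob_mask, small_phantom):
        phantom, _ = small_phantom
        oset = tm.OrientationSet(increment_deg=0.0, angles_deg=np.zeros((1, 3)))
        job = tm.MatchJob(
            tomogram=phantom, template=blob_template, mask=blob_mask,
            orientations=oset, wedge=WEDGE,
        )
        out = tm.run_match(job)
        single = tm.lcc_single_orientation(phantom, blob_template, blob_mask, WEDGE)
        valid = out.valid_mask()
        np.testing.assert_allclose(out.lcc_max.data[valid], single.data[valid], atol=1e-9)
        assert np.all(out.angle_index == 0)

    def test_max_non_decreasing_under_set_extension(self, blob_template, blob_mask,
                                                    small_phantom):
        phantom, _ = small_phantom
        base = generate_orientation_set(55.0)
        extended = tm.OrientationSet(
            increment_deg=base.increment_deg,
            angles_deg=np.vstack([base.angles_deg, [[17.0, 33.0, 240.0]]]),
        )
        job_a = tm.MatchJob(tomogram=phantom, template=blob_template, mask=blob_mask,
                            orientations=base, wedge=WEDGE)
        job_b = tm.MatchJob(tomogram=phantom, template=blob_template, mask=blob_mask,
                            orientations=extended, wedge=WEDGE)
        a = tm.run_match(job_a)
        b = tm.run_match(job_b)
        valid = a.valid_mask()
        assert np.all(b.lcc_max.data[valid] >= a.lcc_max.data[valid] - 1e-12)

    def test_phantom_particle_found_at_planted_orientation(self, blob_template, blob_mask):
        # one particle whose orientation is a member of the searched set
        oset = generate_orientation_set(45.0)
        planted = oset[13]
        rotated = tm.rotate_volume(blob_template, planted)
        vol = np.zeros((48, 48, 48))
        pos = (25, 22, 24)
        vol[pos[0] - 8 : pos[0] + 8, pos[1] - 8 : pos[1] + 8, pos[2] - 8 : pos[2] + 8] = (
            rotated.data
        )
        import scipy.fft

        from tomomatch.template import build_wedge_mask

        w = build_wedge_mask(vol.shape, WEDGE)[..., : vol.shape[2] // 2 + 1]
        vol = scipy.fft.irfftn(scipy.fft.rfftn(vol) * w, s=vol.shape)
        job = tm.MatchJob(
            tomogram=tm.DensityVolume(vol, 14.0), template=blob_template,
            mask=blob_mask, orientations=oset, wedge=WEDGE,
        )
        out = tm.run_match(job)
        best = np.unravel_index(np.argmax(out.lcc_max.data), out.lcc_max.shape)
        assert np.linalg.norm(np.array(best) - np.array(pos)) <= 1.0
        q_found = quaternions_from_matrices(euler_to_matrix(oset[int(out.angle_index[best])]))
        q_true = quaternions_from_matrices(euler_to_matrix(planted))
        assert float(geodesic_distance(q_found, q_true)) <= 45.0

    def test_affine_intensity_invariance(self, tiny_job, small_phantom):
        phantom, _ = small_phantom
        ref = tm.run_match(tiny_job)
        shifted = tm.MatchJob(
            tomogram=tm.DensityVolume(2.5 * phantom.data + 4.0, phantom.voxel_size),
            template=tiny_job.template, mask=tiny_job.mask,
            orientations=tiny_job.orientations, wedge=tiny_job.wedge,
        )
        out = tm.run_match(shifted)
        valid = ref.valid_mask()
        np.testing.assert_allclose(out.lcc_max.data[valid], ref.lcc_max.data[valid], atol=1e-5)

    def test_margin_flagged_invalid(self, tiny_job):
        out = tm.run_match(tiny_job)
        assert out.valid_margin == 8
        assert np.all(out.lcc_max.data[:8, :, :] == -1.0)
        assert np.all(out.lcc_max.data[:, :, -8:] == -1.0)
        valid = out.valid_mask()
        assert np.abs(out.lcc_max.data[valid]).max() <= 1.0 + 1e-6

    def test_empty_orientations_rejected(self, blob_template, blob_mask, small_phantom):
        phantom, _ = small_phantom
        with pytest.raises(ValueError):
            tm.OrientationSet(increment_deg=1.0, angles_deg=np.empty((0, 3)))

    def test_median_score_improves_with_finer_sampling(self, blob_template, blob_mask):
        # qualitative mirror of the angular-sampling study: finer increments
        # raise the LCCmax on particles with random true orientations
        spec = tm.PhantomSpec(
            template=blob_template, box=(96, 96, 96), n_particles=8,
            min_separation=300.0, snr=1.0, wedge=WEDGE, seed=9,
        )
        phantom, truth = tm.generate_phantom(spec)
        medians = []
        for inc in (35.0, 25.0, 15.0):
            job = tm.MatchJob(
                tomogram=phantom, template=blob_template, mask=blob_mask,
                orientations=generate_orientation_set(inc), wedge=WEDGE,
            )
            scores, _ = score_at_positions(job, truth.positions().astype(int))
            medians.append(float(np.median(scores)))
        assert medians[0] <= medians[1] <= medians[2]


@pytest.fixture(scope="module")
def phantom96(blob_template):
    spec = tm.PhantomSpec(
        template=blob_template, box=(96, 96, 96), n_particles=8,
        min_separation=300.0, snr=1.0, wedge=WEDGE, seed=5,
    )
    return tm.generate_phantom(spec)[0]


@pytest.fixture(scope="module")
def job96(blob_template, blob_mask, phantom96):
    return tm.MatchJob(
        tomogram=phantom96, template=blob_template, mask=blob_mask,
        orientations=generate_orientation_set(55.0), wedge=WEDGE,
    )


@pytest.fixture(scope="module")
def serial(job96):
    return tm.run_match(job96)


class TestSplitAndMerge:
    def test_subvolume_split_matches_serial(self, job96, serial):
        split_job = tm.MatchJob(
            tomogram=job96.tomogram, template=job96.template, mask=job96.mask,
            orientations=job96.orientations, wedge=job96.wedge, split=(2, 2, 1),
        )
        merged = tm.split_and_merge(split_job)
        valid = serial.valid_mask()
        assert np.abs(merged.lcc_max.data - serial.lcc_max.data)[valid].max() < 1e-6
        np.testing.assert_array_equal(merged.angle_index[valid], serial.angle_index[valid])

    def test_angle_split_exactly_matches_serial(self, job96, serial):
        merged = tm.split_and_merge(job96, angle_partitions=2)
        np.testing.assert_array_equal(merged.lcc_max.data, serial.lcc_max.data)
        np.testing.assert_array_equal(merged.angle_index, serial.angle_index)

    def test_trivial_split_is_identical(self, job96, serial):
        merged = tm.split_and_merge(job96)
        np.testing.assert_array_equal(merged.lcc_max.data, serial.lcc_max.data)
        np.testing.assert_array_equal(merged.angle_index, serial.angle_index)

    def test_oversplit_rejected(self, blob_template, blob_mask):
        vol = tm.DensityVolume(np.random.default_rng(0).normal(size=(24, 24, 24)), 14.0)
        job = tm.MatchJob(
            tomogram=vol, template=blob_template, mask=blob_mask,
            orientations=generate_orientation_set(90.0), wedge=None, split=(25, 1, 1),
        )
        with pytest.raises(ValueError):
            tm.split_and_merge(job)


class TestScoreAtPositions:
    def test_agrees_with_full_search(self, blob_template, blob_mask, small_phantom):
        phantom, truth = small_phantom
        job = tm.MatchJob(
            tomogram=phantom, template=blob_template, mask=blob_mask,
            orientations=generate_orientation_set(40.0), wedge=WEDGE,
        )
        full = tm.run_match(job)
        pos = truth.positions().astype(int)
        direct, idx = score_at_positions(job, pos)
        grid = full.lcc_max.data[tuple(pos.T)]
        np.testing.assert_allclose(direct, grid, atol=1e-9)
        np.testing.assert_array_equal(idx, full.angle_index[tuple(pos.T)])

    def test_border_positions_rejected(self, blob_template, blob_mask, small_phantom):
        phantom, _ = small_phantom
        job = tm.MatchJob(
            tomogram=phantom, template=blob_template, mask=blob_mask,
            orientations=generate_orientation_set(90.0), wedge=None,
        )
        with pytest.raises(ValueError):
            score_at_positions(job, np.array([[2, 30, 30]]))
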