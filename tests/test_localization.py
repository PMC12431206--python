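import numpy as np
import pytest
from scipy.constants import c as C_LIGHT

from radarhrv.localization import (
    BeamEnergyMaps,
    beam_angles,
    beam_to_cartesian,
    beamform_energy,
    compute_beam_maps,
    fuse_and_detect,
    localize,
    mti_filter,
    range_doppler_map,
)
from radarhrv.synthesis import DisplacementTrace, RadarCube, RadarConfig, Scene, synthesize_cube

from conftest import make_trace


def _cube_from_data(data, config):
    return RadarCube(data=data, config=config)


def _static_trace(n, frame_rate=20.0):
    t = np.arange(n) / frame_rate
    z = np.zeros_like(t)
    return DisplacementTrace(t=t, xb=z, xh=z, e=z, beat_times=np.array([]))


class TestMti:
    def test_static_cube_cancels_exactly(self):
        cfg = RadarConfig(n_samples=8, n_chirps=2, rx_positions=((0.0, 0.0),))
        rng = np.random.default_rng(0)
        frame = rng.standard_normal((1, 2, 1, 8)) + 1j * rng.standard_normal((1, 2, 1, 8))
        data = np.repeat(frame, 5, axis=0)
        out = mti_filter(_cube_from_data(data, cfg))
        assert out.n_frames == 4
        np.testing.assert_array_equal(out.data, 0.0)

    def test_linearity(self):
        cfg = RadarConfig(n_samples=8, n_chirps=2, rx_positions=((0.0, 0.0),))
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 2, 1, 8)) * (1 + 0j)
        b = rng.standard_normal((4, 2, 1, 8)) * (1 + 0j)
        lhs = mti_filter(_cube_from_data(a + b, cfg)).data
        rhs = mti_filter(_cube_from_data(a, cfg)).data + mti_filter(_cube_from_data(b, cfg)).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_single_frame_raises(self):
        cfg = RadarConfig(n_samples=8, n_chirps=2, rx_positions=((0.0, 0.0),))
        with pytest.raises(ValueError):
            mti_filter(_cube_from_data(np.ones((1, 2, 1, 8), complex), cfg))

    def test_clutter_attenuated_at_least_20_db(self, small_cube_scene):
        cube, _ = small_cube_scene
        clutter_pos = cube.scene.clutter[0][0]
        k = round(np.linalg.norm(clutter_pos) / cube.config.range_resolution)

        def bin_energy(c):
            X = np.fft.fft(c.data, axis=-1)
            return np.sum(np.abs(X[..., k]) ** 2) / c.n_frames

        filtered = mti_filter(cube)
        attenuation_db = 10.0 * np.log10(bin_energy(cube) / bin_energy(filtered))
        assert attenuation_db >= 20.0


class TestRangeDoppler:
    def test_zero_input_zero_map(self):
        cfg = RadarConfig(n_samples=16, n_chirps=4, rx_positions=((0.0, 0.0),))
        rd = range_doppler_map(_cube_from_data(np.zeros((3, 4, 1, 16), complex), cfg), rx=0)
        np.testing.assert_array_equal(rd.energy, 0.0)

    def test_tone_peaks_at_predicted_range_bin(self):
        cfg = RadarConfig(n_samples=32, n_chirps=4, rx_positions=((0.0, 0.0),))
        bin_idx = 7
        m = np.arange(32)
        tone = np.exp(2j * np.pi * bin_idx * m / 32)
        data = np.tile(tone, (2, 4, 1, 1))
        rd = range_doppler_map(_cube_from_data(data, cfg), rx=0)
        range_profile = rd.energy.sum(axis=1)
        assert np.argmax(range_profile) == bin_idx

    def test_parseval_energy_conservation(self):
        cfg = RadarConfig(n_samples=16, n_chirps=8, rx_positions=((0.0, 0.0),))
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 8, 1, 16)) + 1j * rng.standard_normal((2, 8, 1, 16))
        rd = range_doppler_map(_cube_from_data(data, cfg), rx=0)
        from scipy.signal.windows import blackmanharris

        wf = blackmanharris(16)
        ws = blackmanharris(8)
        windowed = data[:, :, 0, :] * wf[None, None, :] * ws[None, :, None]
        assert rd.energy.sum() == pytest.approx(np.sum(np.abs(windowed) ** 2), rel=1e-10)


class TestBeamforming:
    def _tone_cube(self, u, n_ant=4):
        cfg = RadarConfig(
            n_samples=16,
            n_chirps=2,
            n_beam=64,
            rx_positions=tuple((float(i), 0.0) for i in range(n_ant)),
        )
        ant = np.arange(n_ant)
        sig = np.exp(1j * np.pi * ant * u)
        data = np.tile(sig[None, None, :, None], (3, 2, 1, 16)).astype(complex)
        return _cube_from_data(data, cfg)

    def test_broadside_target_peaks_at_center_beam(self):
        cube = self._tone_cube(u=0.0)
        _, agg = beamform_energy(cube, "horizontal")
        beam_profile = agg.sum(axis=0)
        assert np.argmax(beam_profile) == cube.config.n_beam // 2

    def test_map_max_is_one_after_normalization(self):
        cube = self._tone_cube(u=0.1)
        _, agg = beamform_energy(cube, "horizontal")
        assert agg.max() == pytest.approx(1.0)

    def test_10_degree_target_within_one_beam(self):
        theta = np.deg2rad(10.0)
        cube = self._tone_cube(u=np.sin(theta), n_ant=8)
        _, agg = beamform_energy(cube, "horizontal")
        best = np.argmax(agg.sum(axis=0))
        angles = beam_angles(cube.config)
        step = angles[1] - angles[0]
        assert abs(angles[best] - theta) <= step

    def test_single_antenna_axis_raises(self):
        cfg = RadarConfig(n_samples=8, n_chirps=2, rx_positions=((0.0, 0.0), (1.0, 0.0)))
        cube = _cube_from_data(np.ones((2, 2, 2, 8), complex), cfg)
        with pytest.raises(ValueError):
            beamform_energy(cube, "vertical")


class TestFuseAndDetect:
    def _maps(self, ehor, ever):
        nf = 3
        return BeamEnergyMaps(
            ehor=ehor,
            ever=ever,
            ehor_frames=np.tile(ehor[None], (nf, 1, 1)),
            ever_frames=np.tile(ever[None], (nf, 1, 1)),
        )

    def test_single_dominant_cell(self):
        cfg = RadarConfig(n_samples=16, n_chirps=2, n_beam=8)
        ehor = np.full((16, 8), 1e-3)
        ever = np.full((16, 8), 1e-3)
        ehor[5, 2] = 1.0
        ever[5, 6] = 1.0
        clusters = fuse_and_detect(self._maps(ehor, ever), cfg, eta=0.5, min_samples=1)
        assert len(clusters) == 1
        assert clusters[0].representative == (2, 6, 5)

    def test_eta_one_keeps_only_argmax(self):
        cfg = RadarConfig(n_samples=16, n_chirps=2, n_beam=8)
        rng = np.random.default_rng(0)
        ehor = rng.uniform(0.01, 0.5, (16, 8))
        ever = rng.uniform(0.01, 0.5, (16, 8))
        ehor[3, 1] = 1.0
        ever[3, 4] = 1.0
        clusters = fuse_and_detect(self._maps(ehor, ever), cfg, eta=1.0, min_samples=1)
        members = np.concatenate([c.members for c in clusters])
        assert len(members) == 1
        assert tuple(members[0]) == (1, 4, 3)

    def test_two_separated_blobs_give_two_clusters(self):
        cfg = RadarConfig(n_samples=32, n_chirps=2, n_beam=16)
        ehor = np.full((32, 16), 1e-4)
        ever = np.full((32, 16), 1e-4)
        for k, i, j in ((5, 2, 3), (25, 12, 13)):
            ehor[k - 1 : k + 2, i - 1 : i + 2] = 1.0
            ever[k - 1 : k + 2, j - 1 : j + 2] = 1.0
        clusters = fuse_and_detect(
            self._maps(ehor, ever), cfg, eta=0.5, eps=2.0, min_samples=4
        )
        assert len(clusters) == 2

    def test_empty_candidates_gives_empty_list(self):
        cfg = RadarConfig(n_samples=8, n_chirps=2, n_beam=4)
        zero = np.zeros((8, 4))
        assert fuse_and_detect(self._maps(zero, zero), cfg) == []


class TestBeamToCartesian:
    def test_boresight_is_on_axis(self):
        cfg = RadarConfig(n_beam=64, n_samples=64)
        for mode in ("physical", "linear"):
            x, y, z = beam_to_cartesian(32, 32, 10, cfg, mode=mode)
            assert x == pytest.approx(0.0, abs=1e-12)
            assert z == pytest.approx(0.0, abs=1e-12)

    def test_linear_range_spacing(self):
        cfg = RadarConfig(bandwidth=1e9, n_beam=64, n_samples=64)
        _, y, _ = beam_to_cartesian(32, 32, 10, cfg, mode="linear")
        assert y == pytest.approx(10.0 * C_LIGHT / (4.0 * 1e9), rel=1e-12)

    def test_y_monotone_in_range_index(self):
        cfg = RadarConfig(n_beam=16, n_samples=32)
        ys = [beam_to_cartesian(8, 8, k, cfg)[1] for k in range(32)]
        assert np.all(np.diff(ys) > 0)

    def test_out_of_bounds_raises(self):
        cfg = RadarConfig(n_beam=8, n_samples=16)
        with pytest.raises(ValueError):
            beam_to_cartesian(8, 0, 0, cfg)
        with pytest.raises(ValueError):
            beam_to_cartesian(0, 0, 16, cfg)


class TestEndToEnd:
    def test_recovers_target_position(self, small_cube_scene):
        cube, target = small_cube_scene
        clusters = localize(cube)
        assert clusters, "target not detected"
        est = np.array(clusters[0].cartesian)
        tgt = np.array(target)
        r = np.linalg.norm(tgt)
        # one range bin in y; one beam step (in meters at the target range) in x/z
        angles = beam_angles(cube.config)
        beam_step_m = r * (np.sin(angles[1]) - np.sin(angles[0]))
        assert abs(est[1] - tgt[1]) <= cube.config.range_resolution
        assert abs(est[0] - tgt[0]) <= beam_step_m
        assert abs(est[2] - tgt[2]) <= beam_step_m

    def test_detection_invariant_to_cube_scaling(self, small_cube_scene):
        cube, _ = small_cube_scene
        scaled = RadarCube(data=cube.data * 37.0, config=cube.config)
        a = localize(cube)
        b = localize(scaled)
        assert a[0].representative == b[0].representative

    def test_energy_volume_is_rank_one_per_range_slice(self, small_cube_scene):
        cube, _ = small_cube_scene
        maps = compute_beam_maps(mti_filter(cube))
        e3d = np.einsum("ki,kj->ijk", maps.ehor, maps.ever)
        k = np.argmax(maps.ehor.max(axis=1))
        slice_k = e3d[:, :, k]
        s = np.linalg.svd(slice_k, compute_uv=False)
        assert s[1] <= 1e-10 * s[0]
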