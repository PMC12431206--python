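"""3D target localization from a radar cube.

Pipeline: MTI clutter cancellation along slow time, windowed range and
Doppler FFTs, delay-and-sum digital beamforming on the horizontal and
vertical subarrays, fusion of the two range-angle energy maps into a 3D
energy volume, thresholding, and DBSCAN clustering of candidate cells.
Each cluster's representative cell is the member that most often carries
the cluster's per-frame energy maximum, ties broken by total energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np
from scipy.signal.windows import blackmanharris
from sklearn.cluster import DBSCAN
from scipy.constants import c as C_LIGHT

from radarhrv.synthesis import RadarConfig, RadarCube

__all__ = [
    "RangeDopplerMap",
    "BeamEnergyMaps",
    "TargetCluster",
    "mti_filter",
    "range_doppler_map",
    "beamform_energy",
    "fuse_and_detect",
    "beam_to_cartesian",
    "beam_angles",
    "localize",
]


@dataclass
class RangeDopplerMap:
    """Energy over [range bin x Doppler bin] for one antenna, summed over frames."""

    energy: np.ndarray
    rx: int
    window: str = "blackmanharris"


@dataclass
class BeamEnergyMaps:
    """Normalized range-angle energy on both axes plus per-frame maps."""

    ehor: np.ndarray          # [range bin, horizontal beam], max 1
    ever: np.ndarray          # [range bin, vertical beam], max 1
    ehor_frames: np.ndarray   # [frame, range bin, beam] un-normalized
    ever_frames: np.ndarray


@dataclass
class TargetCluster:
    members: np.ndarray           # (m, 3) array of (i, j, k) indices
    representative: tuple         # (i, j, k)
    cartesian: tuple              # (x, y, z) in m

    @property
    def n_members(self) -> int:
        return len(self.members)


def mti_filter(cube: RadarCube) -> RadarCube:
    """Two-pulse (first-difference) canceller along the frame axis.

    Static returns cancel exactly; the output has one fewer frame.
    """
    if cube.n_frames < 2:
        raise ValueError("MTI requires at least 2 frames")
    return RadarCube(
        data=np.diff(cube.data, axis=0),
        config=cube.config,
        scene=cube.scene,
        truth=cube.truth,
    )


def range_doppler_map(cube: RadarCube, rx: int) -> RangeDopplerMap:
    """Windowed range FFT then windowed Doppler (chirp) FFT, energy summed over frames.

    Both FFTs use a Blackman-Harris window and orthonormal scaling so the
    map energy equals the windowed time-domain energy (Parseval).
    """
    x = cube.data[:, :, rx, :]  # [frame, chirp, sample]
    w_fast = blackmanharris(cube.config.n_samples)
    w_slow = blackmanharris(cube.config.n_chirps)
    xr = np.fft.fft(x * w_fast[None, None, :], axis=-1, norm="ortho")
    xrd = np.fft.fft(xr * w_slow[None, :, None], axis=1, norm="ortho")
    energy = np.sum(np.abs(xrd) ** 2, axis=0).T  # [range, doppler]
    return RangeDopplerMap(energy=energy, rx=rx)


def beam_angles(config: RadarConfig) -> np.ndarray:
    """Steering angle grid: n_beam angles, boresight at index n_beam // 2."""
    n = config.n_beam
    i = np.arange(n)
    return config.theta_max * (2.0 * i - n) / n


def _range_fft(cube: RadarCube) -> np.ndarray:
    w = blackmanharris(cube.config.n_samples)
    return np.fft.fft(cube.data * w, axis=-1)  # [frame, chirp, rx, range]


def beamform_energy(cube: RadarCube, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Delay-and-sum beam energy on one axis.

    Returns ``(per_frame, aggregate)`` where ``per_frame`` is
    [frame, range bin, beam] energy summed over chirps and ``aggregate``
    sums over frames and is max-normalized to 1.
    """
    idx, coords = cube.config.axis_antennas(axis)
    if len(idx) < 2:
        raise ValueError(f"beamforming on {axis} axis needs >= 2 antennas")
    thetas = beam_angles(cube.config)
    xr = _range_fft(cube)[:, :, idx, :]  # [frame, chirp, ant, range]
    # conjugate-matched weights [ant, beam]; half-wavelength units -> pi * d * sin(theta)
    steer = np.exp(-1j * np.pi * coords[:, None] * np.sin(thetas)[None, :])
    beams = np.einsum("fcar,ab->fcbr", xr, steer)
    per_frame = np.sum(np.abs(beams) ** 2, axis=1)  # [frame, beam, range]
    per_frame = np.transpose(per_frame, (0, 2, 1))  # [frame, range, beam]
    aggregate = per_frame.sum(axis=0)
    m = aggregate.max()
    if m > 0:
        aggregate = aggregate / m
    return per_frame, aggregate


def compute_beam_maps(cube: RadarCube) -> BeamEnergyMaps:
    hor_frames, ehor = beamform_energy(cube, "horizontal")
    ver_frames, ever = beamform_energy(cube, "vertical")
    return BeamEnergyMaps(
        ehor=ehor, ever=ever, ehor_frames=hor_frames, ever_frames=ver_frames
    )


def fuse_and_detect(
    maps: BeamEnergyMaps,
    config: RadarConfig,
    eta: float = 0.5,
    eps: float = 2.0,
    min_samples: int = 4,
    coordinate_mode: str = "physical",
) -> list[TargetCluster]:
    """Fuse axis energies into a 3D volume, threshold, and cluster.

    The volume E3D[i, j, k] = Ehor[k, i] * Ever[k, j] is max-normalized;
    cells with energy >= eta * max are candidates and are clustered with
    DBSCAN in (i, j, k) index space.  Within each cluster, for every frame
    the member cell with the largest instantaneous fused energy is found;
    the representative is the cell winning most frames (ties broken by
    larger aggregate energy).
    """
    e3d = np.einsum("ki,kj->ijk", maps.ehor, maps.ever)
    m = e3d.max()
    if m <= 0:
        return []
    e3d = e3d / m
    cand = np.argwhere(e3d >= eta)
    if len(cand) == 0:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(cand)
    clusters: list[TargetCluster] = []
    for lab in sorted(set(labels)):
        if lab == -1:
            continue
        members = cand[labels == lab]
        ii, jj, kk = members[:, 0], members[:, 1], members[:, 2]
        # per-frame fused energy at member cells only
        ef = maps.ehor_frames[:, kk, ii] * maps.ever_frames[:, kk, jj]  # [frame, m]
        wins = np.bincount(np.argmax(ef, axis=1), minlength=len(members))
        agg = e3d[ii, jj, kk]
        best = max(range(len(members)), key=lambda q: (wins[q], agg[q]))
        rep = tuple(int(v) for v in members[best])
        clusters.append(
            TargetCluster(
                members=members,
                representative=rep,
                cartesian=beam_to_cartesian(*rep, config, mode=coordinate_mode),
            )
        )
    clusters.sort(key=lambda c: -e3d[c.representative])
    return clusters


def beam_to_cartesian(
    i: int, j: int, k: int, config: RadarConfig, mode: str = "physical"
) -> tuple[float, float, float]:
    """Convert volume indices (horizontal beam, vertical beam, range) to meters.

    ``mode="physical"`` places the cell at range k * c/(2B) along the beam
    direction given by the steering-angle grid (consistent with the FFT
    and beamformer used here).  ``mode="linear"`` applies the simplified
    linear index mapping x = xdis*(i - Nbeam/2), y = ydis*k,
    z = zdis*(j - Nbeam/2) with ydis = c/(4B) and
    xdis = zdis = c*N*tan(theta_max)/(4B*Nbeam).
    """
    n_beam = config.n_beam
    if not (0 <= i < n_beam and 0 <= j < n_beam and 0 <= k < config.n_samples):
        raise ValueError("indices out of volume bounds")
    if mode == "linear":
        ydis = C_LIGHT / (4.0 * config.bandwidth)
        xdis = zdis = (
            C_LIGHT * config.n_samples * np.tan(config.theta_max)
            / (4.0 * config.bandwidth * n_beam)
        )
        off = n_beam // 2
        return (xdis * (i - off), ydis * k, zdis * (j - off))
    if mode != "physical":
        raise ValueError("mode must be 'physical' or 'linear'")
    r = k * config.range_resolution
    thetas = beam_angles(config)
    ux, uz = np.sin(thetas[i]), np.sin(thetas[j])
    uy2 = max(1.0 - ux**2 - uz**2, 0.0)
    return (r * ux, r * np.sqrt(uy2), r * uz)


def localize(
    cube: RadarCube,
    eta: float = 0.5,
    eps: float = 2.0,
    min_samples: int = 4,
    coordinate_mode: str = "physical",
) -> list[TargetCluster]:
    """End-to-end localization: MTI -> beamform both axes -> fuse -> cluster."""
    filtered = mti_filter(cube)
    maps = compute_beam_maps(filtered)
    return fuse_and_detect(
        maps, cube.config, eta=eta, eps=eps, min_samples=min_samples,
        coordinate_mode=coordinate_mode,
    )
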