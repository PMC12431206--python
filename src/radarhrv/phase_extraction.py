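"""Phase demodulation: radar cube + target cell -> unwrapped phase y(t).

For each frame the range FFT is beamformed toward the target cluster's
steering angles, the complex value at the target range bin is taken, and
its four-quadrant arctangent phase is unwrapped (adding multiples of 2*pi
wherever a successive difference exceeds pi) and mean-removed.  A
displacement of d meters changes the two-way carrier phase by
4*pi*d/lambda_c, so phase is directly convertible to displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal.windows import blackmanharris

from radarhrv.localization import TargetCluster, beam_angles
from radarhrv.synthesis import RadarCube

__all__ = ["PhaseSignal", "extract_phase_series", "variance_filter"]


@dataclass
class PhaseSignal:
    """Unwrapped, mean-removed phase time series at one target cell."""

    t: np.ndarray
    y: np.ndarray                  # rad
    source_cell: tuple             # (i, j, k)
    wavelength: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")

    @property
    def variance(self) -> float:
        return float(np.var(self.y))

    @property
    def displacement_mm(self) -> np.ndarray:
        """Phase converted to radial displacement (mm)."""
        return self.y * self.wavelength / (4.0 * np.pi) * 1000.0

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def extract_phase_series(cube: RadarCube, cluster: TargetCluster) -> PhaseSignal:
    """Demodulate the unwrapped phase at a cluster's representative cell.

    Uses one slow-time sample per frame (the first chirp), beamforming all
    antennas toward the cluster's horizontal/vertical steering angles.
    """
    i, j, k = cluster.representative
    cfg = cube.config
    if not (0 <= k < cfg.n_samples and 0 <= i < cfg.n_beam and 0 <= j < cfg.n_beam):
        raise ValueError("cluster representative outside cube bounds")
    thetas = beam_angles(cfg)
    ux, uz = np.sin(thetas[i]), np.sin(thetas[j])
    rx = np.asarray(cfg.rx_positions, dtype=float)
    steer = np.exp(-1j * np.pi * (rx[:, 0] * ux + rx[:, 1] * uz))  # [rx]
    w = blackmanharris(cfg.n_samples)
    # [frame, rx, sample] -> range FFT -> pick bin k -> combine antennas
    xr = np.fft.fft(cube.data[:, 0, :, :] * w, axis=-1)[:, :, k]
    z = xr @ steer
    phase = np.unwrap(np.angle(z))
    t = np.arange(cube.n_frames) / cfg.frame_rate
    return PhaseSignal(
        t=t, y=phase - phase.mean(), source_cell=(i, j, k), wavelength=cfg.wavelength
    )


def variance_filter(
    signals: Sequence[PhaseSignal], threshold: float = 1e-4
) -> list[PhaseSignal]:
    """Keep phase series whose variance reaches ``threshold`` (rad^2).

    Low-variance series correspond to static reflections without vital
    signs; ordering is preserved and an empty result is allowed.
    """
    return [s for s in signals if s.variance >= threshold]
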