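"""Synthesis of chest-wall displacement and raw FMCW radar cubes.

The displacement model treats the thoracic wall as a superposition of a
quasi-periodic respiratory component (piecewise inhalation/exhalation
curve, 0.1-0.5 Hz, millimetre scale), a quasi-periodic cardiac component
(five-stage model following the mechanical phases of the cardiac cycle,
0.8-2.0 Hz, 0.01-0.2 mm scale) and band-limited micro-motion noise.
The radar model renders the displacement into complex intermediate-
frequency (IF) samples of a de-chirped FMCW radar: a point target at
range R produces a fast-time tone whose frequency encodes R and whose
carrier phase term 4*pi*R/lambda_c carries the sub-wavelength vibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.constants import c as C_LIGHT

__all__ = [
    "VitalSignParams",
    "RadarConfig",
    "Scene",
    "DisplacementTrace",
    "RadarCube",
    "NoiseConfig",
    "respiration_waveform",
    "heartbeat_waveform",
    "generate_ibi_sequence",
    "beat_train",
    "compose_displacement",
    "synthesize_cube",
    "save_cube",
    "load_cube",
    "trace_to_csv",
]


@dataclass(frozen=True)
class VitalSignParams:
    """Physiological constants of the respiration and heartbeat models.

    Respiration (amplitude ``ar_mm``) is split into an inhalation phase of
    duration ``ti_s`` (quadratic filling) and an exhalation phase of
    duration ``te_s`` (exponential emptying with time constant ``tau_s``);
    the respiratory cycle is ``tr_s = ti_s + te_s``.

    The heartbeat template over one inter-beat interval ``trr_s`` has five
    stages delimited by ``tp_s < tpr_s < tqrs_s < tst_s < trr_s``:
    quadratic atrial rise to ``kp_mm``, atrial plateau, Gaussian
    ventricular-contraction rise to ``kqrs_mm``, ventricular plateau, and
    exponential relaxation back to baseline with rate ``lambda_relax``
    (must satisfy lambda_relax >= 5/(trr_s - tst_s) so the relaxation is
    essentially complete within the beat).  Stage boundaries are stored as
    fractions of ``trr_s`` so that a beat can be re-scaled to any IBI.
    """

    ar_mm: float = 4.0
    ti_s: float = 1.6
    te_s: float = 2.4
    tau_s: float = 0.8
    kp_mm: float = 0.04
    kqrs_mm: float = 0.12
    mean_ibi_s: float = 0.85
    ibi_jitter_sd_s: float = 0.03
    tp_frac: float = 0.10
    tpr_frac: float = 0.15
    tqrs_frac: float = 0.25
    tst_frac: float = 0.45
    lambda_relax: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.ti_s, self.te_s, self.tau_s) <= 0:
            raise ValueError("ti_s, te_s and tau_s must be positive")
        if not (0 < self.kp_mm < self.kqrs_mm):
            raise ValueError("need 0 < kp_mm < kqrs_mm (sigma_qrs2 undefined otherwise)")
        if not (0 < self.tp_frac < self.tpr_frac < self.tqrs_frac < self.tst_frac < 1):
            raise ValueError("stage fractions must satisfy 0 < Tp < TPR < TQRS < TST < TRR")
        if self.mean_ibi_s <= 0:
            raise ValueError("mean_ibi_s must be positive")
        if self.ibi_jitter_sd_s < 0:
            raise ValueError("ibi_jitter_sd_s must be nonnegative")
        if self.lambda_relax is None:
            object.__setattr__(self, "lambda_relax", self.lambda_min)
        elif self.lambda_relax < self.lambda_min - 1e-12:
            raise ValueError(
                f"lambda_relax must be >= 5/(TRR - TST) = {self.lambda_min:.4g}"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def tr_s(self) -> float:
        """Respiratory cycle duration (s)."""
        return self.ti_s + self.te_s

    @property
    def trr_s(self) -> float:
        """Nominal beat-to-beat interval used for the heartbeat template (s)."""
        return self.mean_ibi_s

    @property
    def tp_s(self) -> float:
        return self.tp_frac * self.trr_s

    @property
    def tpr_s(self) -> float:
        return self.tpr_frac * self.trr_s

    @property
    def tqrs_s(self) -> float:
        return self.tqrs_frac * self.trr_s

    @property
    def tst_s(self) -> float:
        return self.tst_frac * self.trr_s

    @property
    def lambda_min(self) -> float:
        return 5.0 / (self.trr_s - self.tst_s)

    @property
    def sigma_qrs2(self) -> float:
        """Gaussian width parameter (s^2) forcing continuity at TPR and TQRS."""
        return (self.tpr_s - self.tqrs_s) ** 2 / (2.0 * np.log(self.kqrs_mm / self.kp_mm))


@dataclass(frozen=True)
class RadarConfig:
    """FMCW radar front-end and array geometry.

    ``rx_positions`` are (horizontal, vertical) receive-antenna coordinates
    in units of half a carrier wavelength.  The default is an L-shaped
    three-element array (two horizontal, two vertical elements sharing the
    corner) at half-wavelength pitch, matching compact 60 GHz sensors.
    """

    fc: float = 60e9
    bandwidth: float = 1e9
    n_samples: int = 64
    n_chirps: int = 8
    frame_rate: float = 20.0
    rx_positions: tuple = ((0.0, 0.0), (1.0, 0.0), (0.0, 1.0))
    n_beam: int = 64
    theta_max: float = np.deg2rad(60.0)

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.frame_rate < 10.0:
            raise ValueError("frame_rate must be >= 10 Hz (>= 5x max heart frequency)")
        if len(self.rx_positions) < 1:
            raise ValueError("need at least one receive antenna")

    @property
    def wavelength(self) -> float:
        return C_LIGHT / self.fc

    @property
    def range_resolution(self) -> float:
        """Range-bin spacing of the fast-time FFT, c/(2B) (m)."""
        return C_LIGHT / (2.0 * self.bandwidth)

    @property
    def max_range(self) -> float:
        return self.n_samples * self.range_resolution

    def axis_antennas(self, axis: str) -> tuple[np.ndarray, np.ndarray]:
        """Indices and half-wavelength coordinates of the subarray on an axis.

        The horizontal subarray consists of elements on the horizontal rail
        (vertical coordinate equal to the array minimum), and conversely.
        """
        pos = np.asarray(self.rx_positions, dtype=float)
        if axis == "horizontal":
            on_axis = np.isclose(pos[:, 1], pos[:, 1].min())
            coords = pos[:, 0]
        elif axis == "vertical":
            on_axis = np.isclose(pos[:, 0], pos[:, 0].min())
            coords = pos[:, 1]
        else:
            raise ValueError("axis must be 'horizontal' or 'vertical'")
        idx = np.flatnonzero(on_axis)
        return idx, coords[idx]


@dataclass(frozen=True)
class Scene:
    """Reflector layout and noise levels for cube synthesis."""

    target_position: tuple = (0.0, 1.0, 0.0)
    target_amplitude: float = 1.0
    clutter: tuple = ()  # sequence of ((x, y, z), reflectivity)
    snr_db: float = 20.0
    micromotion_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if np.linalg.norm(self.target_position) <= 0:
            raise ValueError("target range must be positive")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


@dataclass
class DisplacementTrace:
    """Ground-truth chest-wall displacement decomposition, y = xb + xh + e."""

    t: np.ndarray
    xb: np.ndarray
    xh: np.ndarray
    e: np.ndarray
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.xb) == len(self.xh) == len(self.e) == n):
            raise ValueError("component arrays must share the time grid length")
        dt = np.diff(self.t)
        if n > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("t must be strictly increasing and uniform")

    @property
    def y(self) -> np.ndarray:
        return self.xb + self.xh + self.e

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class RadarCube:
    """Complex IF samples indexed [frame, chirp, rx, sample] plus metadata."""

    data: np.ndarray
    config: RadarConfig
    scene: Optional[Scene] = None
    truth: Optional[DisplacementTrace] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D [frame, chirp, rx, sample]")
        f, ch, rx, s = self.data.shape
        if rx != len(self.config.rx_positions) or s != self.config.n_samples:
            raise ValueError("data shape inconsistent with config")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("cube contains non-finite samples")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# Displacement waveforms
# ---------------------------------------------------------------------------

def respiration_waveform(params: VitalSignParams, t: np.ndarray) -> np.ndarray:
    """Respiratory chest-wall displacement (mm) on the time grid ``t``.

    Inhalation ([0, Ti], quadratic rise to ``ar_mm``) followed by
    exhalation ([Ti, Tr], exponential decay back to 0).  Periodic with the
    respiratory cycle Tr and continuous at both branch boundaries.
    """
    t = np.asarray(t, dtype=float)
    ar, ti, te, tau, tr = params.ar_mm, params.ti_s, params.te_s, params.tau_s, params.tr_s
    tm = np.mod(t, tr)
    inhale = -ar / (ti * te) * tm**2 + ar * tr / (ti * te) * tm
    exhale = ar / (1.0 - np.exp(-te / tau)) * (
        np.exp(-(tm - ti) / tau) - np.exp(-te / tau)
    )
    return np.where(tm <= ti, inhale, exhale)


def heartbeat_waveform(
    params: VitalSignParams,
    t: np.ndarray,
    *,
    as_printed_tail: bool = False,
) -> np.ndarray:
    """Cardiac chest-wall displacement template (mm) on ``t``.

    Five stages over one interval TRR: quadratic atrial rise to Kp on
    [0, Tp]; atrial plateau Kp on [Tp, TPR]; Gaussian ventricular rise to
    KQRS on [TPR, TQRS] (the Gaussian width is fixed by continuity at both
    ends); ventricular plateau KQRS on [TQRS, TST]; exponential relaxation
    to 0 on [TST, TRR].  The default relaxation branch is normalized so it
    starts at KQRS and reaches exactly 0 at TRR; ``as_printed_tail``
    selects an alternative un-normalized form that does not return to
    baseline at TRR.
    """
    t = np.asarray(t, dtype=float)
    kp, kqrs = params.kp_mm, params.kqrs_mm
    tp, tpr, tqrs, tst, trr = (
        params.tp_s, params.tpr_s, params.tqrs_s, params.tst_s, params.trr_s,
    )
    lam = params.lambda_relax
    s2 = params.sigma_qrs2
    tm = np.mod(t, trr)

    out = np.empty_like(tm)
    m1 = tm <= tp
    m2 = (tm > tp) & (tm <= tpr)
    m3 = (tm > tpr) & (tm <= tqrs)
    m4 = (tm > tqrs) & (tm <= tst)
    m5 = tm > tst

    out[m1] = -kp / tp**2 * tm[m1] ** 2 + 2.0 * kp / tp * tm[m1]
    out[m2] = kp
    out[m3] = kqrs * np.exp(-((tm[m3] - tqrs) ** 2) / (2.0 * s2))
    out[m4] = kqrs
    decay_end = np.exp(-lam * (trr - tst))
    if as_printed_tail:
        out[m5] = kqrs * (1.0 - np.exp(-lam * (tm[m5] - tst)) - decay_end) / (1.0 - decay_end)
    else:
        out[m5] = kqrs * (np.exp(-lam * (tm[m5] - tst)) - decay_end) / (1.0 - decay_end)
    return out


def generate_ibi_sequence(
    mean_ibi: float,
    jitter_sd: float,
    n_beats: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n_beats`` inter-beat intervals (s) with Gaussian jitter.

    IBIs are independent normal draws around ``mean_ibi`` clipped to
    [0.5, 1.5] * mean_ibi so pathological tails cannot produce
    non-physiological beats.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ibis = rng.normal(mean_ibi, jitter_sd, size=n_beats)
    return np.clip(ibis, 0.5 * mean_ibi, 1.5 * mean_ibi)


def beat_train(
    params: VitalSignParams,
    ibis: Sequence[float],
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile per-beat heartbeat templates over ``t``.

    Beat k occupies [sum of previous IBIs, + IBI_k); within each beat all
    stage boundaries scale linearly with IBI_k / TRR, i.e. the template is
    evaluated at local time stretched by TRR / IBI_k.  Returns
    ``(displacement_mm, beat_times)`` where beat times mark the centre of
    each beat's maximal (ventricular) plateau [TQRS, TST], the location a
    peak detector reports for the template.  Samples beyond the last beat
    are at baseline 0.
    """
    ibis = np.asarray(ibis, dtype=float)
    if ibis.size == 0:
        raise ValueError("ibis must be nonempty")
    t = np.asarray(t, dtype=float)
    onsets = np.concatenate([[0.0], np.cumsum(ibis)])
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    if t[-1] - t[0] + dt < ibis[0]:
        raise ValueError("time grid shorter than one beat")
    xh = np.zeros_like(t)
    rel = t - t[0]
    beat_idx = np.searchsorted(onsets, rel, side="right") - 1
    in_train = (beat_idx >= 0) & (beat_idx < len(ibis))
    bi = beat_idx[in_train]
    local = (rel[in_train] - onsets[bi]) * (params.trr_s / ibis[bi])
    # local time is within [0, TRR); evaluate the unit template there
    xh[in_train] = heartbeat_waveform(params, local)
    beat_times = t[0] + onsets[:-1] + 0.5 * (params.tqrs_frac + params.tst_frac) * ibis
    return xh, beat_times


@dataclass(frozen=True)
class NoiseConfig:
    """Micro-motion noise specification for :func:`compose_displacement`.

    Exactly one of ``sd_mm`` (absolute RMS in mm) or ``snr_db`` (heartbeat
    RMS over noise RMS, dB) should be set.  Noise is Gaussian, low-pass
    filtered below ``cutoff_hz`` to emulate slow involuntary body motion.
    """

    sd_mm: Optional[float] = None
    snr_db: Optional[float] = None
    cutoff_hz: float = 8.0


def _bandlimited_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n)
    nyq = fs / 2.0
    if cutoff_hz < nyq * 0.999:
        sos = sps.butter(4, cutoff_hz / nyq, btype="low", output="sos")
        e = sps.sosfiltfilt(sos, e)
    return e


def compose_displacement(
    params: VitalSignParams,
    ibis: Sequence[float],
    noise: NoiseConfig,
    t: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> DisplacementTrace:
    """Compose y = xb + xh + e on the grid ``t``, retaining ground truth."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.asarray(t, dtype=float)
    xb = respiration_waveform(params, t)
    xh, beat_times = beat_train(params, ibis, t)
    if noise.sd_mm is not None and noise.snr_db is not None:
        raise ValueError("set only one of sd_mm and snr_db")
    if noise.sd_mm is not None:
        target_rms = noise.sd_mm
    elif noise.snr_db is not None:
        target_rms = float(np.sqrt(np.mean(xh**2))) / 10.0 ** (noise.snr_db / 20.0)
    else:
        target_rms = 0.0
    if target_rms > 0:
        fs = 1.0 / (t[1] - t[0])
        e = _bandlimited_noise(len(t), fs, noise.cutoff_hz, rng)
        e *= target_rms / np.sqrt(np.mean(e**2))
    else:
        e = np.zeros_like(t)
    return DisplacementTrace(t=t, xb=xb, xh=xh, e=e, beat_times=beat_times)


# ---------------------------------------------------------------------------
# Radar cube rendering
# ---------------------------------------------------------------------------

def _point_target_if(
    config: RadarConfig,
    position: np.ndarray,
    amplitude: float,
    displacement_m: np.ndarray,
) -> np.ndarray:
    """IF samples [frame, rx, sample] of a point target with radial motion.

    The de-chirped return of a target at range R is a complex fast-time
    tone at (R / range_resolution) FFT bins with carrier phase
    4*pi*R/lambda; each receive element adds a steering phase
    pi*(dh*ux + dv*uz) for direction cosines (ux, uz) at half-wavelength
    element coordinates (dh, dv).
    """
    pos = np.asarray(position, dtype=float)
    r0 = float(np.linalg.norm(pos))
    ux, uz = pos[0] / r0, pos[2] / r0
    r_t = r0 + displacement_m  # [frame]
    if np.any(r_t >= config.max_range) or np.any(r_t <= 0):
        raise ValueError("target outside unambiguous range")
    m = np.arange(config.n_samples)
    rx = np.asarray(config.rx_positions, dtype=float)
    steer = np.exp(1j * np.pi * (rx[:, 0] * ux + rx[:, 1] * uz))  # [rx]
    tone = np.exp(
        1j * 2.0 * np.pi
        * (r_t[:, None] / config.range_resolution)
        * m[None, :] / config.n_samples
    )  # [frame, sample]
    carrier = np.exp(1j * 4.0 * np.pi * r_t / config.wavelength)  # [frame]
    return amplitude * carrier[:, None, None] * steer[None, :, None] * tone[:, None, :]


def synthesize_cube(
    config: RadarConfig,
    scene: Scene,
    trace: DisplacementTrace,
    seed: int | np.random.Generator = 0,
) -> RadarCube:
    """Render a displacement trace into a complex FMCW radar cube.

    One frame is emitted per time sample of ``trace`` (slow-time sampling
    at the frame rate); chirps within a frame see the same displacement.
    Static clutter reflectors add constant tones; receiver noise is
    complex white Gaussian with power set by ``scene.snr_db`` relative to
    the target's per-sample signal power.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_frames = len(trace.t)
    per_frame = _point_target_if(
        config,
        np.asarray(scene.target_position, float),
        scene.target_amplitude,
        trace.y / 1000.0,
    )
    for pos, refl in scene.clutter:
        per_frame = per_frame + _point_target_if(
            config, np.asarray(pos, float), refl, np.zeros(n_frames)
        )
    data = np.repeat(per_frame[:, None, :, :], config.n_chirps, axis=1)
    noise_power = scene.target_amplitude**2 / 10.0 ** (scene.snr_db / 10.0)
    if noise_power > 0:
        sigma = np.sqrt(noise_power / 2.0)
        data = data + sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return RadarCube(data=data.astype(np.complex64), config=config, scene=scene, truth=trace)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_cube(path, cube: RadarCube) -> None:
    """Write a cube to HDF5: /cube dataset, /config attrs, /truth datasets."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data, dtype=np.complex64)
        g = f.create_group("config")
        cfg = cube.config
        g.attrs["fc"] = cfg.fc
        g.attrs["bandwidth"] = cfg.bandwidth
        g.attrs["n_samples"] = cfg.n_samples
        g.attrs["n_chirps"] = cfg.n_chirps
        g.attrs["frame_rate"] = cfg.frame_rate
        g.attrs["n_beam"] = cfg.n_beam
        g.attrs["theta_max"] = cfg.theta_max
        g.create_dataset("rx_positions", data=np.asarray(cfg.rx_positions, float))
        if cube.truth is not None:
            tg = f.create_group("truth")
            for name in ("t", "xb", "xh", "e", "beat_times"):
                tg.create_dataset(name, data=getattr(cube.truth, name))
            tg.create_dataset("y", data=cube.truth.y)


def load_cube(path) -> RadarCube:
    import h5py

    with h5py.File(path, "r") as f:
        data = f["cube"][...]
        g = f["config"]
        config = RadarConfig(
            fc=float(g.attrs["fc"]),
            bandwidth=float(g.attrs["bandwidth"]),
            n_samples=int(g.attrs["n_samples"]),
            n_chirps=int(g.attrs["n_chirps"]),
            frame_rate=float(g.attrs["frame_rate"]),
            rx_positions=tuple(map(tuple, g["rx_positions"][...])),
            n_beam=int(g.attrs["n_beam"]),
            theta_max=float(g.attrs["theta_max"]),
        )
        truth = None
        if "truth" in f:
            tg = f["truth"]
            truth = DisplacementTrace(
                t=tg["t"][...], xb=tg["xb"][...], xh=tg["xh"][...],
                e=tg["e"][...], beat_times=tg["beat_times"][...],
            )
    return RadarCube(data=data, config=config, truth=truth)


def trace_to_csv(path, trace: DisplacementTrace) -> None:
    """Export a displacement trace as CSV with columns t,xb,xh,e,y."""
    import pandas as pd

    pd.DataFrame(
        {"t": trace.t, "xb": trace.xb, "xh": trace.xh, "e": trace.e, "y": trace.y}
    ).to_csv(path, index=False)
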