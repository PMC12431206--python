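"""Second-order spectral sparse separation with Lagrangian multipliers.

Splits a demodulated phase signal y(t) = xb(t) + xh(t) + e(t) into the
respiratory component xb and the cardiac component xh.  Both components
are quasi-periodic, hence approximately low-rank in the eigenstructure of
their Hankel (trajectory) covariance matrices; the cardiac component
additionally carries the sharp rise/fall structure emphasized by the
second derivative of y.  The objective combines eigenvalue-tail sparsity
penalties for both components, a second-derivative structural term for
the heartbeat, and a data-fidelity term:

    J = alpha_b * sum_{i>n} lam_b_i^2 + alpha_h * sum_{j>n} lam_h_j^2
        + beta * ||D2 y - xh||^2 + gamma * ||y - xb - xh||^2

subject to lam_i = (1/K) ||H^T(x) u_i||^2 for each component, enforced
with Lagrange multipliers mu that are updated by gradient ascent.  Each
iteration: (1) closed-form eigenvalue update lam = -mu/(2 alpha), clipped
at zero; (2) fresh eigendecomposition of the component's Hankel
covariance; (3) rank-n reconstruction by diagonal averaging; (4) signal
updates from the stationarity conditions of the Lagrangian; (5) multiplier
ascent step.  Convergence is declared when both components agree with
their low-rank reconstructions to within eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.linalg import eigh, hankel

__all__ = [
    "SeparationConfig",
    "SeparationResult",
    "build_hankel",
    "inverse_hankel",
    "covariance_eig",
    "hankel_adjoint_apply",
    "second_difference",
    "objective_value",
    "separate",
    "bandpass_baseline",
]


# ---------------------------------------------------------------------------
# Hankel primitives
# ---------------------------------------------------------------------------

def build_hankel(x: np.ndarray, L: int) -> np.ndarray:
    """Trajectory matrix H[l, k] = x[l + k] of shape (L, K), K = T - L + 1."""
    x = np.asarray(x, dtype=float)
    T = len(x)
    if not (1 <= L <= T):
        raise ValueError("need 1 <= L <= len(x)")
    return hankel(x[:L], x[L - 1 :])


def _antidiag_indices(L: int, K: int) -> np.ndarray:
    return np.add.outer(np.arange(L), np.arange(K)).ravel()


def _antidiag_counts(L: int, K: int) -> np.ndarray:
    return np.bincount(_antidiag_indices(L, K), minlength=L + K - 1)


def inverse_hankel(H: np.ndarray) -> np.ndarray:
    """Diagonal averaging: x[t] = mean of H[i, j] over anti-diagonal i + j = t."""
    H = np.asarray(H, dtype=float)
    if H.size == 0:
        raise ValueError("empty matrix")
    L, K = H.shape
    idx = _antidiag_indices(L, K)
    sums = np.bincount(idx, weights=H.ravel(), minlength=L + K - 1)
    return sums / _antidiag_counts(L, K)


def _antidiag_sum(M: np.ndarray) -> np.ndarray:
    """Anti-diagonal sums (un-averaged inverse Hankel), length L + K - 1."""
    L, K = M.shape
    return np.bincount(_antidiag_indices(L, K), weights=M.ravel(), minlength=L + K - 1)


def covariance_eig(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of R = (1/K) H(x) H(x)^T, eigenvalues descending.

    R is symmetric positive semidefinite; eigenvalues are clipped at zero
    against round-off and satisfy lam_i = (1/K) ||H^T(x) u_i||^2.
    """
    H = build_hankel(x, L)
    K = H.shape[1]
    R = (H @ H.T) / K
    lam, U = eigh(R)
    order = np.argsort(lam)[::-1]
    return np.clip(lam[order], 0.0, None), U[:, order]


def hankel_adjoint_apply(S: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Adjoint of the linear map x -> H^T(x) u, applied to S.

    For x of length T = L + K - 1, the map x -> H^T(x) u has Jacobian D
    with D^T S given by the full correlation
    (D^T S)(t) = sum_k S(k) u(t - k), i.e. the anti-diagonal sums of the
    rank-1 matrix u S^T.
    """
    S = np.asarray(S, dtype=float)
    u = np.asarray(u, dtype=float)
    if S.ndim != 1 or u.ndim != 1:
        raise ValueError("S and u must be 1-D")
    return np.convolve(u, S)


def second_difference(y: np.ndarray, dt: float) -> np.ndarray:
    """Central second difference with reflected boundaries, scaled by 1/dt^2."""
    yp = np.pad(y, 1, mode="reflect")
    return (yp[:-2] - 2.0 * yp[1:-1] + yp[2:]) / dt**2


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass
class SeparationConfig:
    """Hyperparameters of the separation algorithm.

    ``L`` is the Hankel window length in samples (default: 4 s worth of
    samples, long enough to span several heartbeats); ``n`` the retained
    eigen-rank (default: smallest rank capturing ``energy_frac`` of the
    eigen-energy of the initialized cardiac component).  ``alpha_b``,
    ``alpha_h`` weight the eigenvalue-tail sparsity penalties, ``beta``
    the second-derivative structural term, ``gamma`` data fidelity,
    ``rho`` the multiplier ascent step, and ``eps`` the convergence
    tolerance on the reconstruction residuals.  The sparsity weights and
    step size must keep the multiplier feedback contractive
    (rho < 4 * alpha, and alpha small enough that the low-rank coupling
    gain alpha * lam_1 * L / (K * gamma) stays well below one for
    unit-variance input); the defaults satisfy this with a wide margin
    and were calibrated on the synthetic recovery suite.

    Initialization: the respiratory component starts from a harmonic-
    series least-squares fit at the estimated respiratory fundamental
    (capturing the harmonics that overlap the heart band), falling back
    to a plain low-pass when no dominant respiratory line exists; the
    cardiac component starts from the heart-band residual.
    """

    L: Optional[int] = None
    n: Optional[int] = None
    alpha_b: float = 0.01
    alpha_h: float = 0.01
    beta: float = 1e-5
    gamma: float = 10.0
    rho: float = 1e-5
    eps: float = 1e-6
    max_iter: int = 30
    resp_band: tuple = (0.1, 0.5)
    heart_band: tuple = (0.8, 2.0)
    energy_frac: float = 0.95
    n_harmonics: int = 12
    rank_truncate: bool = True   # False: sum reconstruction over all N components
    return_reconstruction: bool = True

    def __post_init__(self) -> None:
        if min(self.alpha_b, self.alpha_h, self.beta, self.gamma, self.rho) <= 0:
            raise ValueError("all weights must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class SeparationResult:
    xb: np.ndarray
    xh: np.ndarray
    n_iter: int
    converged: bool
    delta_b: np.ndarray          # residual trace per iteration
    delta_h: np.ndarray
    eigvals_b: np.ndarray        # final covariance spectra
    eigvals_h: np.ndarray
    rank: int
    L: int


def _sos_filter(y: np.ndarray, fs: float, band: tuple, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if btype == "low":
        wn = min(band[0] / nyq, 0.99)
    else:
        lo, hi = band
        if not (0 < lo < hi):
            raise ValueError("invalid band")
        wn = [lo / nyq, min(hi / nyq, 0.99)]
        if wn[0] >= wn[1]:
            raise ValueError("band exceeds Nyquist range")
    sos = sps.butter(4, wn, btype=btype, output="sos")
    return sps.sosfiltfilt(sos, y)


def bandpass_baseline(
    y: np.ndarray, fs: float, band: tuple = (0.8, 2.0)
) -> np.ndarray:
    """Zero-phase Butterworth band-pass heart-band baseline estimator."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2.0):
        raise ValueError("band must lie within (0, fs/2)")
    return _sos_filter(np.asarray(y, float), fs, band, "band")


def _rank_from_energy(lam: np.ndarray, frac: float) -> int:
    total = lam.sum()
    if total <= 0:
        return 1
    return int(np.searchsorted(np.cumsum(lam) / total, frac) + 1)


def _spectral_peak(y: np.ndarray, fs: float, band: tuple) -> tuple[float, float]:
    """(frequency, magnitude) of the windowed-FFT peak inside ``band``.

    The peak bin is refined by parabolic interpolation of the magnitude
    spectrum, giving frequency resolution well below one bin.
    """
    T = len(y)
    spec = np.abs(np.fft.rfft(y * np.hanning(T)))
    f = np.fft.rfftfreq(T, 1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        return 0.0, 0.0
    k = int(np.flatnonzero(mask)[np.argmax(spec[mask])])
    if 0 < k < len(spec) - 1:
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2.0 * b + c
        delta = 0.5 * (a - c) / denom if abs(denom) > 1e-30 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (k + delta) * fs / T, float(spec[k])


def _harmonic_fit(
    y: np.ndarray, fs: float, f0: float, fmax: float, n_harmonics: int
) -> np.ndarray:
    """Least-squares fit of a harmonic series at fundamental ``f0``.

    Models the quasi-periodic respiration together with the harmonics
    that leak into the heart band; harmonics above ``fmax`` are excluded.
    """
    T = len(y)
    t = np.arange(T) / fs
    cols = [np.ones(T)]
    for h in range(1, n_harmonics + 1):
        fh = h * f0
        if fh > fmax or fh >= fs / 2.0:
            break
        cols.append(np.cos(2.0 * np.pi * fh * t))
        cols.append(np.sin(2.0 * np.pi * fh * t))
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef


def objective_value(
    xb: np.ndarray,
    xh: np.ndarray,
    y: np.ndarray,
    config: SeparationConfig,
    dt: float,
    L: Optional[int] = None,
    n: Optional[int] = None,
) -> float:
    """Evaluate the separation objective J(xb, xh, n)."""
    L = L if L is not None else config.L
    if L is None:
        raise ValueError("L must be given via argument or config")
    lam_b, _ = covariance_eig(xb, L)
    lam_h, _ = covariance_eig(xh, L)
    if n is None:
        n = config.n if config.n is not None else L
    d2y = second_difference(y, dt)
    return float(
        config.alpha_b * np.sum(lam_b[n:] ** 2)
        + config.alpha_h * np.sum(lam_h[n:] ** 2)
        + config.beta * np.sum((d2y - xh) ** 2)
        + config.gamma * np.sum((y - xb - xh) ** 2)
    )


# ---------------------------------------------------------------------------
# Main algorithm
# ---------------------------------------------------------------------------

def separate(
    y: np.ndarray,
    fs: float,
    config: Optional[SeparationConfig] = None,
) -> SeparationResult:
    """Separate a phase signal into respiration xb and heartbeat xh.

    ``y`` is mean-removed and amplitude-normalized internally (outputs are
    rescaled back), the components are initialized by band-limiting y to
    the respiratory (low-pass) and cardiac (band-pass) bands, and the
    five-step multiplier iteration runs until both components match their
    rank-n Hankel reconstructions within ``eps`` or ``max_iter`` is hit
    (non-convergence is reported via the ``converged`` flag, not raised).
    """
    config = config or SeparationConfig()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    T = len(y)
    dt = 1.0 / fs
    L = config.L if config.L is not None else max(2, int(round(4.0 * fs)))
    if not (2 <= L <= T // 2):
        raise ValueError("need 2 <= L <= len(y) // 2")
    K = T - L + 1
    N = L

    offset = y.mean()
    scale = y.std()
    if scale == 0.0:
        z = np.zeros(T)
        return SeparationResult(
            xb=z, xh=z.copy(), n_iter=1, converged=True,
            delta_b=np.zeros(1), delta_h=np.zeros(1),
            eigvals_b=np.zeros(N), eigvals_h=np.zeros(N), rank=1, L=L,
        )
    yn = (y - offset) / scale

    # initialization: respiration as a harmonic-series fit at the estimated
    # fundamental (so its in-band harmonics start on the respiratory side),
    # unless no dominant respiratory line exists; heart as band residual
    f0, resp_mag = _spectral_peak(yn, fs, config.resp_band)
    _, heart_mag = _spectral_peak(yn, fs, config.heart_band)
    if resp_mag >= heart_mag and f0 > 0:
        xb = _harmonic_fit(
            yn, fs, f0, config.heart_band[1] + 0.5, config.n_harmonics
        )
    else:
        xb = _sos_filter(yn, fs, (config.resp_band[1],), "low")
    xh = _sos_filter(yn - xb, fs, config.heart_band, "band")
    lam_h0, _ = covariance_eig(xh, L)
    lam_b0, _ = covariance_eig(xb, L)
    if config.n is not None:
        n = int(config.n)
    else:
        n = _rank_from_energy(lam_h0, config.energy_frac)
    n = int(np.clip(n, 1, N))
    # the respiratory reconstruction needs a deeper rank: its harmonic
    # ladder spans orders of magnitude in eigen-energy, and the weak
    # harmonics inside the heart band must stay on the respiratory side
    n_b = int(np.clip(_rank_from_energy(lam_b0, 0.999), n, N))

    mu_b = np.zeros(N)
    mu_h = np.zeros(N)
    d2y = second_difference(yn, dt)
    counts = _antidiag_counts(L, K)

    delta_b_trace: list[float] = []
    delta_h_trace: list[float] = []
    converged = False
    xbr = xb.copy()
    xhr = xh.copy()

    for it in range(1, config.max_iter + 1):
        # (1) closed-form eigenvalue update, clipped to the PSD cone
        lam_b = np.clip(-mu_b / (2.0 * config.alpha_b), 0.0, None)
        lam_h = np.clip(-mu_h / (2.0 * config.alpha_h), 0.0, None)

        # (2) fresh eigenvectors from the current component covariances
        w_b, U_b = covariance_eig(xb, L)
        w_h, U_h = covariance_eig(xh, L)

        # (3) rank-limited reconstruction: the sqrt(K lam) factors of the
        # right-singular-vector definition cancel, leaving the projection
        # sum_i u_i (H^T x u_i)^T; diagonal averaging maps back to a signal
        rank_b, rank_h = (n_b, n) if config.rank_truncate else (N, N)
        S_b = build_hankel(xb, L).T @ U_b          # (K, N)
        S_h = build_hankel(xh, L).T @ U_h
        xbr = _antidiag_sum(U_b[:, :rank_b] @ S_b[:, :rank_b].T) / counts
        xhr = _antidiag_sum(U_h[:, :rank_h] @ S_h[:, :rank_h].T) / counts

        # (4) stationarity updates for the signals
        grad_b = _antidiag_sum(U_b @ np.diag(mu_b) @ S_b.T)
        grad_h = _antidiag_sum(U_h @ np.diag(mu_h) @ S_h.T)
        xb_new = yn - xh - grad_b / (K * config.gamma)
        xh_new = (
            config.gamma * (yn - xb) + config.beta * d2y + grad_h / K
        ) / (config.gamma + config.beta)

        # (5) multiplier ascent on the eigenvalue constraints
        mu_b = mu_b + config.rho * (lam_b - np.sum(S_b**2, axis=0) / K)
        mu_h = mu_h + config.rho * (lam_h - np.sum(S_h**2, axis=0) / K)

        if not (np.all(np.isfinite(xb_new)) and np.all(np.isfinite(xh_new))):
            raise FloatingPointError("separation iterates diverged to non-finite values")

        db = float(np.sum((xbr - xb_new) ** 2))
        dh = float(np.sum((xhr - xh_new) ** 2))
        delta_b_trace.append(db)
        delta_h_trace.append(dh)
        xb, xh = xb_new, xh_new
        if db < config.eps and dh < config.eps:
            converged = True
            break

    out_b, out_h = (xbr, xhr) if config.return_reconstruction else (xb, xh)
    lam_b_fin, _ = covariance_eig(out_b, L)
    lam_h_fin, _ = covariance_eig(out_h, L)
    return SeparationResult(
        xb=out_b * scale,
        xh=out_h * scale,
        n_iter=it,
        converged=converged,
        delta_b=np.asarray(delta_b_trace),
        delta_h=np.asarray(delta_h_trace),
        eigvals_b=lam_b_fin,
        eigvals_h=lam_h_fin,
        rank=n,
        L=L,
    )
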