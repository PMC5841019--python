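"""Linear inverse operators: MNE, sLORETA, eLORETA, LCMV.

All four methods produce a linear kernel mapping average-referenced sensor
data (microvolts) to free-orientation dipole moments (3 components per
source).  Formulas follow the canonical published definitions:

MNE      K = R L~' (L~ R L~' + lam^2 I)^-1 W, with W the noise whitener,
         L~ = W L, and R the diagonal depth-weighted source prior
         (||L~_i||^2)^(-depth), scaled so that lam^2 follows the 1/snr^2
         convention on the whitened problem.
sLORETA  MNE kernel with depth 0, then per-source standardization by the
         3x3 resolution block S_i = K_i L_i: K_i <- S_i^(-1/2) K_i.
eLORETA  iteratively reweighted: M = (L W^-1 L' + lam H)^+ with H the
         average-reference centering matrix, W_i = (L_i' M L_i)^(1/2),
         repeated to a fixed point; K = W^-1 L' M.
LCMV     per-source W_i = (L_i' C^-1 L_i)^-1 L_i' C^-1 with the data
         covariance Tikhonov-regularized: C <- C + gamma tr(C)/n I.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .containers import Recording, SourceActivity
from .forward import Leadfield

METHODS = ("mne", "sloreta", "eloreta", "lcmv")


@dataclass
class InverseConfig:
    method: str = "eloreta"
    lam: float | None = None      # if set, lam^2 is the Tikhonov weight
    snr: float = 5.0              # else lam^2 = 1/snr^2
    depth: float = 0.0            # depth-weighting exponent in [0, 1]
    lcmv_gamma: float = 0.05      # Tikhonov fraction of mean eigenvalue
    eloreta_lam_frac: float = 0.05  # lam = frac * trace(B)/n_channels
    eloreta_tol: float = 1e-6
    eloreta_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError("depth must be in [0, 1]")

    @classmethod
    def for_method(cls, method: str) -> "InverseConfig":
        """Published default settings per method."""
        if method == "mne":
            return cls(method="mne", lam=0.1, snr=5.0, depth=0.5)
        if method == "sloreta":
            return cls(method="sloreta", lam=None, snr=5.0, depth=0.0)
        if method == "eloreta":
            return cls(method="eloreta")
        if method == "lcmv":
            return cls(method="lcmv", lcmv_gamma=0.05)
        raise ValueError(f"unknown method {method!r}")

    @property
    def lam2(self) -> float:
        return self.lam**2 if self.lam is not None else 1.0 / self.snr**2


@dataclass
class InverseOperator:
    """Linear estimator: kernel (n_sources, 3, n_channels)."""

    kernel: np.ndarray
    method: str
    config: InverseConfig
    n_iterations: int = 0
    residuals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 3 or self.kernel.shape[1] != 3:
            raise ValueError("kernel must be (n_sources, 3, n_channels)")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel must be finite")

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_channels(self) -> int:
        return self.kernel.shape[2]

    @property
    def kernel2d(self) -> np.ndarray:
        return self.kernel.reshape(self.n_sources * 3, self.n_channels)


def estimate_noise_covariance(rec: Recording, split: float = 40.0) -> np.ndarray:
    """Diagonal noise covariance from per-channel high-frequency variance.

    The variance of the residual above ``split`` Hz is rescaled by the band
    fraction so that for white noise the estimate converges to sigma^2 I.
    """
    eeg = rec.data[rec.eeg_indices]
    nyq = rec.fs / 2.0
    split = min(split, 0.8 * nyq)
    sos = sps.butter(4, split / nyq, btype="low", output="sos")
    resid = eeg - sps.sosfiltfilt(sos, eeg, axis=1)
    scale = nyq / (nyq - split)
    return np.diag(resid.var(axis=1) * scale)


def estimate_data_covariance(rec: Recording) -> np.ndarray:
    eeg = rec.data[rec.eeg_indices]
    eeg = eeg - eeg.mean(axis=1, keepdims=True)
    return (eeg @ eeg.T) / eeg.shape[1]


def _whitener(noise_cov: np.ndarray) -> np.ndarray:
    noise_cov = 0.5 * (noise_cov + noise_cov.T)
    evals, evecs = np.linalg.eigh(noise_cov)
    if evals.max() <= 0:
        raise np.linalg.LinAlgError(
            "noise covariance is singular; regularize it (e.g. add a small "
            "multiple of the identity)")
    floor = evals.max() * 1e-12
    if evals.min() < floor:
        raise np.linalg.LinAlgError(
            "noise covariance is (near-)singular; regularize it before "
            "whitening")
    return evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T


def _sym_inv_sqrt_3x3(blocks: np.ndarray, inverse: bool = True) -> np.ndarray:
    """Batched symmetric (inverse) square root of (n, 3, 3) PSD blocks."""
    blocks = 0.5 * (blocks + np.swapaxes(blocks, 1, 2))
    evals, evecs = np.linalg.eigh(blocks)
    floor = np.maximum(evals[:, -1:], 1e-300) * 1e-12
    evals = np.maximum(evals, floor)
    power = -0.5 if inverse else 0.5
    d = evals**power
    return np.einsum("nij,nj,nkj->nik", evecs, d, evecs)


def _batched_inv_3x3(blocks: np.ndarray) -> np.ndarray:
    blocks = 0.5 * (blocks + np.swapaxes(blocks, 1, 2))
    evals, evecs = np.linalg.eigh(blocks)
    floor = np.maximum(evals[:, -1:], 1e-300) * 1e-12
    evals = np.maximum(evals, floor)
    return np.einsum("nij,nj,nkj->nik", evecs, 1.0 / evals, evecs)


def compute_mne_operator(L: Leadfield, noise_cov: np.ndarray,
                         cfg: InverseConfig | None = None) -> InverseOperator:
    """Depth-weighted, noise-prewhitened minimum-norm operator."""
    cfg = cfg or InverseConfig.for_method("mne")
    W = _whitener(noise_cov)
    n_ch, n_src = L.n_channels, L.n_sources
    Lw = W @ L.matrix                              # (C, 3S)
    Lw3 = Lw.reshape(n_ch, n_src, 3)
    col_norm2 = np.einsum("csa,csa->s", Lw3, Lw3)  # ||L~_i||_F^2 per source
    r = col_norm2 ** (-cfg.depth)
    # scale prior so trace(L~ R L~') = n_channels (1/snr^2 convention)
    r *= n_ch / np.sum(r * col_norm2)
    R = np.repeat(r, 3)
    G = (Lw * R) @ Lw.T + cfg.lam2 * np.eye(n_ch)
    K = (R[:, None] * Lw.T) @ np.linalg.solve(G, W)
    return InverseOperator(kernel=K.reshape(n_src, 3, n_ch),
                           method="mne", config=cfg)


def compute_sloreta_operator(L: Leadfield, noise_cov: np.ndarray,
                             cfg: InverseConfig | None = None) -> InverseOperator:
    """MNE (no depth weighting) standardized by the 3x3 resolution blocks."""
    cfg = cfg or InverseConfig.for_method("sloreta")
    cfg = replace(cfg, method="sloreta", depth=0.0)
    base = compute_mne_operator(L, noise_cov,
                                replace(cfg, method="mne"))
    K = base.kernel                                   # (S, 3, C)
    S_blocks = np.einsum("sac,csb->sab", K, L.gain)   # K_i L_i
    S_inv_sqrt = _sym_inv_sqrt_3x3(S_blocks)
    K_std = np.einsum("sab,sbc->sac", S_inv_sqrt, K)
    return InverseOperator(kernel=K_std, method="sloreta", config=cfg)


def compute_eloreta_operator(L: Leadfield,
                             cfg: InverseConfig | None = None) -> InverseOperator:
    """Exact low-resolution tomography: iteratively reweighted operator."""
    cfg = cfg or InverseConfig.for_method("eloreta")
    n_ch, n_src = L.n_channels, L.n_sources
    L3 = L.gain                                    # (C, S, 3)
    H = np.eye(n_ch) - np.ones((n_ch, n_ch)) / n_ch
    Wb = np.tile(np.eye(3), (n_src, 1, 1))
    residuals = []
    M = None
    for it in range(cfg.eloreta_max_iter):
        Winv = _batched_inv_3x3(Wb)
        B = np.einsum("csa,sab,dsb->cd", L3, Winv, L3, optimize=True)
        lam = cfg.eloreta_lam_frac * np.trace(B) / n_ch
        M = np.linalg.pinv(B + lam * H, hermitian=True)
        T = np.einsum("csa,cd,dsb->sab", L3, M, L3, optimize=True)
        W_new = _sym_inv_sqrt_3x3(T, inverse=False)
        change = (np.linalg.norm(W_new - Wb, axis=(1, 2))
                  / (np.linalg.norm(Wb, axis=(1, 2)) + 1e-300)).max()
        residuals.append(float(change))
        Wb = W_new
        if change < cfg.eloreta_tol:
            break
    else:
        err = RuntimeError(
            f"eLORETA did not converge in {cfg.eloreta_max_iter} iterations; "
            f"residual history: {residuals}")
        err.residuals = residuals
        raise err
    Winv = _batched_inv_3x3(Wb)
    LtM = np.einsum("csa,cd->sad", L3, M, optimize=True)   # (S, 3, C)
    K = np.einsum("sab,sbc->sac", Winv, LtM)
    return InverseOperator(kernel=K, method="eloreta", config=cfg,
                           n_iterations=len(residuals), residuals=residuals)


def compute_lcmv_operator(L: Leadfield, data_cov: np.ndarray,
                          cfg: InverseConfig | None = None) -> InverseOperator:
    """Unit-gain LCMV beamformer with Tikhonov-regularized data covariance."""
    cfg = cfg or InverseConfig.for_method("lcmv")
    n_ch, n_src = L.n_channels, L.n_sources
    gamma = cfg.lcmv_gamma
    C = 0.5 * (data_cov + data_cov.T) + gamma * (np.trace(data_cov) / n_ch) * np.eye(n_ch)
    evals = np.linalg.eigvalsh(C)
    if evals.min() <= evals.max() * 1e-12:
        raise np.linalg.LinAlgError(
            "data covariance is rank-deficient; use lcmv_gamma > 0")
    Ci = np.linalg.inv(C)
    L3 = L.gain
    CiL = np.einsum("cd,dsa->sac", Ci, L3, optimize=True)   # (S, 3, C) = (L_i' Ci)'
    G = np.einsum("csa,sbc->sab", L3, CiL, optimize=True)   # L_i' Ci L_i
    Ginv = _batched_inv_3x3(G)
    K = np.einsum("sab,sbc->sac", Ginv, CiL)
    return InverseOperator(kernel=K, method="lcmv", config=cfg)


def make_inverse_operator(method: str, leadfield: Leadfield,
                          rec: Recording | None = None,
                          noise_cov: np.ndarray | None = None,
                          data_cov: np.ndarray | None = None,
                          cfg: InverseConfig | None = None) -> InverseOperator:
    """Build the requested operator, estimating covariances from ``rec``."""
    cfg = cfg or InverseConfig.for_method(method)
    if method == "eloreta":
        return compute_eloreta_operator(leadfield, cfg)
    if method in ("mne", "sloreta"):
        if noise_cov is None:
            if rec is None:
                raise ValueError("need a recording or a noise covariance")
            noise_cov = estimate_noise_covariance(rec)
        if method == "mne":
            return compute_mne_operator(leadfield, noise_cov, cfg)
        return compute_sloreta_operator(leadfield, noise_cov, cfg)
    if method == "lcmv":
        if data_cov is None:
            if rec is None:
                raise ValueError("need a recording or a data covariance")
            data_cov = estimate_data_covariance(rec)
        return compute_lcmv_operator(leadfield, data_cov, cfg)
    raise ValueError(f"unknown method {method!r}")


def apply_inverse(rec: Recording, op: InverseOperator) -> SourceActivity:
    """moments = kernel . data, reshaped (sources, 3, samples)."""
    eeg = rec.data[rec.eeg_indices]
    if eeg.shape[0] != op.n_channels:
        raise ValueError(f"recording has {eeg.shape[0]} EEG channels, "
                         f"operator expects {op.n_channels}")
    moments = (op.kernel2d @ eeg).reshape(op.n_sources, 3, -1)
    return SourceActivity(moments=moments, fs=rec.fs, n_sources=op.n_sources)


def source_power(op: InverseOperator, topography: np.ndarray) -> np.ndarray:
    """Per-source power ||K_i x||^2 of a single sensor topography."""
    s = op.kernel2d @ np.asarray(topography, dtype=float).ravel()
    return (s.reshape(op.n_sources, 3) ** 2).sum(axis=1)
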