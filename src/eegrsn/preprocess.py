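"""Raw-recording cleanup.

Pipeline order: bad-channel detection -> interpolation -> 1-80 Hz band-pass
-> artifact-IC removal -> average reference.

Bad channels are flagged from (a) the maximum Pearson correlation of each
EEG channel against all others on 1-40 Hz filtered copies and (b) the
high-frequency noise variance (the residual above 40 Hz), thresholded
robustly across channels.  Artifact ICs are identified from three feature
families: time-course kurtosis, the power spectrum, and correlation with
the hEOG/vEOG/EMG auxiliary channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import Montage, Recording


class DataQualityError(RuntimeError):
    """Raised when a recording is too corrupted to continue."""


@dataclass
class BadChannelReport:
    max_correlation: np.ndarray   # per EEG channel, r in [-1, 1]
    noise_variance: np.ndarray    # per EEG channel, uV^2
    flagged: np.ndarray           # indices into the recording's channel axis
    r_min: float
    v_max_mads: float


@dataclass
class ICArtifactThresholds:
    kurtosis: float = 10.0        # excess kurtosis
    aux_corr: float = 0.5         # max |r| with hEOG/vEOG/EMG
    high_freq_fraction: float = 0.6   # power fraction above 30 Hz


@dataclass
class ICArtifactReport:
    kurtosis: np.ndarray
    low_freq_fraction: np.ndarray     # power below 5 Hz
    high_freq_fraction: np.ndarray    # power above 30 Hz
    one_over_f_deviation: np.ndarray  # rms residual of log-log spectral fit
    aux_correlation: np.ndarray       # (n_ics, n_aux) absolute r
    aux_labels: list
    flags: np.ndarray                 # bool per IC
    criteria: list                    # triggering criterion per IC ("" if clean)
    thresholds: ICArtifactThresholds = field(default_factory=ICArtifactThresholds)
    n_components: int = 0
    converged: bool = True


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = sps.butter(4, cutoff / (fs / 2.0), btype="low", output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def detect_bad_channels(rec: Recording, r_min: float = 0.4,
                        v_max_mads: float = 5.0) -> BadChannelReport:
    """Flag EEG channels with low signal quality.

    A channel is flagged iff its maximum Pearson correlation against every
    other EEG channel (computed on 1-40 Hz filtered copies) falls below
    ``r_min``, or its noise variance (variance of the >40 Hz residual)
    exceeds median + v_max_mads * MAD across channels.
    """
    eeg_idx = rec.eeg_indices
    if eeg_idx.size < 3:
        raise ValueError("need at least 3 EEG channels")
    x = rec.data[eeg_idx]
    hi = min(40.0, 0.4 * rec.fs)
    sos = sps.butter(4, [1.0 / (rec.fs / 2.0), hi / (rec.fs / 2.0)],
                     btype="band", output="sos")
    xf = sps.sosfiltfilt(sos, x, axis=1)
    c = np.corrcoef(xf)
    np.fill_diagonal(c, -1.0)
    max_corr = c.max(axis=1)

    resid = x - _lowpass(x, rec.fs, hi)
    noise_var = resid.var(axis=1)
    med = np.median(noise_var)
    mad = stats.median_abs_deviation(noise_var, scale="normal")
    # floor the MAD so near-identical channels do not trip the threshold
    var_thresh = med + v_max_mads * max(mad, 0.05 * med, 1e-30)

    bad = (max_corr < r_min) | (noise_var > var_thresh)
    if bad.all():
        raise DataQualityError("every EEG channel flagged as bad")
    return BadChannelReport(max_correlation=max_corr, noise_variance=noise_var,
                            flagged=eeg_idx[bad], r_min=r_min,
                            v_max_mads=v_max_mads)


def interpolate_channels(rec: Recording, report: BadChannelReport,
                         montage: Montage, n_neighbors: int = 4) -> Recording:
    """Replace flagged channels by an inverse-distance mean of good neighbors."""
    eeg_idx = rec.eeg_indices
    if report.flagged.size >= 0.2 * eeg_idx.size:
        raise DataQualityError(
            f"{report.flagged.size} of {eeg_idx.size} EEG channels flagged; "
            "too many to interpolate")
    out = rec.copy()
    flagged = set(int(i) for i in report.flagged)
    good = [i for i in eeg_idx if i not in flagged]
    pos = {int(i): montage.positions[int(i)] for i in eeg_idx}
    for b in sorted(flagged):
        d = np.array([np.linalg.norm(pos[b] - pos[g]) for g in good])
        nearest = np.argsort(d)[:n_neighbors]
        w = 1.0 / np.maximum(d[nearest], 1e-12)
        w /= w.sum()
        out.data[b] = w @ rec.data[[good[i] for i in nearest]]
    return out


def bandpass_filter(rec: Recording, low: float = 1.0,
                    high: float = 80.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    if high >= rec.fs / 2.0:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {rec.fs / 2}")
    sos = sps.butter(4, [low / (rec.fs / 2.0), high / (rec.fs / 2.0)],
                     btype="band", output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    return out


def _spectral_features(src: np.ndarray, fs: float):
    """Per-IC Welch-spectrum features (columns of src are IC time courses)."""
    nper = int(min(src.shape[0], 4 * fs))
    f, p = sps.welch(src, fs=fs, nperseg=nper, axis=0)
    total = p.sum(axis=0) + 1e-300
    low_frac = p[f < 5.0].sum(axis=0) / total
    high_frac = p[f > 30.0].sum(axis=0) / total
    sel = (f >= 2.0) & (f <= min(40.0, 0.45 * fs))
    lf = np.log(f[sel])
    lp = np.log(p[sel] + 1e-300)
    dev = np.empty(src.shape[1])
    A = np.column_stack([np.ones_like(lf), lf])
    coef, *_ = np.linalg.lstsq(A, lp, rcond=None)
    resid = lp - A @ coef
    dev[:] = np.sqrt((resid**2).mean(axis=0))
    return low_frac, high_frac, dev


def remove_artifact_ics(rec: Recording,
                        thresholds: ICArtifactThresholds | None = None,
                        seed: int = 0, max_retries: int = 3,
                        max_components: int | None = None
                        ) -> tuple[Recording, ICArtifactReport]:
    """Temporal ICA on the EEG channels; flag and remove artifactual ICs.

    Model order: PCA rank retaining 99.9% of variance (optionally capped by
    ``max_components`` — on dense montages the full rank makes FastICA very
    expensive, and artifact ICs live in the top of the spectrum).  An IC is
    flagged if its excess kurtosis, its correlation with any auxiliary
    channel, or its >30 Hz power fraction exceeds the thresholds.  Flagged
    IC contributions are subtracted; the PCA residual is kept, so removing
    zero ICs reconstructs the input exactly.
    """
    thr = thresholds or ICArtifactThresholds()
    eeg_idx = rec.eeg_indices
    aux_idx = rec.aux_indices
    X = rec.data[eeg_idx].T                     # (T, C)
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = (Xc.T @ Xc) / Xc.shape[0]
    evals = np.linalg.eigvalsh(cov)[::-1]
    frac = np.cumsum(evals) / evals.sum()
    k = int(np.searchsorted(frac, 0.999) + 1)
    k = max(2, min(k, len(eeg_idx)))
    if max_components is not None:
        k = min(k, max_components)

    sources = mixing = None
    converged = False
    for attempt in range(max_retries):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(n_components=k, algorithm="parallel", fun="logcosh",
                          whiten="unit-variance", max_iter=1000, tol=1e-4,
                          random_state=seed + attempt)
            sources = ica.fit_transform(Xc)     # (T, k)
            mixing = ica.mixing_                # (C, k)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = True
            break
    # features
    kurt = stats.kurtosis(sources, axis=0)
    low_frac, high_frac, dev = _spectral_features(sources, rec.fs)
    aux = rec.data[aux_idx]
    aux_labels = [rec.labels[i] for i in aux_idx]
    if aux.size:
        auxc = aux - aux.mean(axis=1, keepdims=True)
        sc = sources - sources.mean(axis=0, keepdims=True)
        denom = np.outer(np.linalg.norm(sc, axis=0),
                         np.linalg.norm(auxc, axis=1)) + 1e-300
        aux_corr = np.abs(sc.T @ auxc.T) / denom      # (k, n_aux)
    else:
        aux_corr = np.zeros((k, 0))

    flags = np.zeros(k, dtype=bool)
    criteria = [""] * k
    for i in range(k):
        if kurt[i] > thr.kurtosis:
            flags[i] = True
            criteria[i] = "kurtosis"
        elif aux_corr.shape[1] and aux_corr[i].max() > thr.aux_corr:
            flags[i] = True
            criteria[i] = "aux-correlation"
        elif high_frac[i] > thr.high_freq_fraction:
            flags[i] = True
            criteria[i] = "high-frequency-power"

    report = ICArtifactReport(
        kurtosis=kurt, low_freq_fraction=low_frac, high_freq_fraction=high_frac,
        one_over_f_deviation=dev, aux_correlation=aux_corr,
        aux_labels=aux_labels, flags=flags, criteria=criteria,
        thresholds=thr, n_components=k, converged=converged)
    if not converged:
        err = RuntimeError("artifact ICA did not converge after "
                           f"{max_retries} restarts")
        err.partial_report = report
        raise err

    out = rec.copy()
    if flags.any():
        artifact = sources[:, flags] @ mixing[:, flags].T   # (T, C)
        out.data[eeg_idx] = (X - artifact).T
    return out, report


def average_reference(rec: Recording) -> Recording:
    """Re-reference EEG channels to their instantaneous mean (idempotent)."""
    out = rec.copy()
    eeg = rec.eeg_indices
    out.data[eeg] -= out.data[eeg].mean(axis=0, keepdims=True)
    out.reference = "average"
    return out


@dataclass
class PreprocessConfig:
    low: float = 1.0
    high: float = 80.0
    r_min: float = 0.4
    v_max_mads: float = 5.0
    ic_thresholds: ICArtifactThresholds = field(default_factory=ICArtifactThresholds)
    seed: int = 0
    run_ica: bool = True


def preprocess(rec: Recording, montage: Montage,
               config: PreprocessConfig | None = None):
    """Full cleanup chain: detect -> interpolate -> filter -> ICA -> avg ref."""
    cfg = config or PreprocessConfig()
    bad = detect_bad_channels(rec, r_min=cfg.r_min, v_max_mads=cfg.v_max_mads)
    rec = interpolate_channels(rec, bad, montage)
    rec = bandpass_filter(rec, cfg.low, cfg.high)
    ic_report = None
    if cfg.run_ica:
        rec, ic_report = remove_artifact_ics(rec, cfg.ic_thresholds, seed=cfg.seed)
    rec = average_reference(rec)
    return rec, bad, ic_report
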