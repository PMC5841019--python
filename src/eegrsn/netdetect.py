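"""Network detection from source activity.

Broadband (1-80 Hz) power time-courses are computed per source on 1-s
moving windows; the number of components is chosen by the minimum
description length criterion on the eigenvalues of the standardized
envelope covariance; spatial FastICA (deflation, tanh contrast, best of 10
restarts by negentropy) yields IC maps independent across the source
dimension; and a greedy no-reuse template matching assigns ICs to labeled
networks by spatial Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import NetworkMap, Recording, SourceActivity
from .inverse import InverseOperator


@dataclass
class PowerEnvelope:
    """Windowed source power: (n_sources, n_windows), (nA*m)^2."""

    power: np.ndarray
    window: float = 1.0   # s
    step: float = 1.0     # s
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be (n_sources, n_windows)")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")

    @property
    def n_sources(self) -> int:
        return self.power.shape[0]

    @property
    def n_windows(self) -> int:
        return self.power.shape[1]


@dataclass
class ICResult:
    maps: np.ndarray          # (n_sources, k), unit variance, skew-positive
    timecourses: np.ndarray   # (k, n_windows)
    k: int
    objectives: np.ndarray    # negentropy proxy per run
    best_run: int


@dataclass
class TemplateSet:
    names: list
    maps: np.ndarray          # (n_sources, n_templates)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.maps.shape[1] != len(self.names):
            raise ValueError("one template column per name required")

    @classmethod
    def from_network_maps(cls, maps: list) -> "TemplateSet":
        return cls(names=[m.name for m in maps],
                   maps=np.column_stack([m.values for m in maps]))


@dataclass
class RSNAssignment:
    assignments: dict         # template name -> (ic index, Pearson r)
    unmatched_ics: list

    def ic_for(self, name: str) -> int:
        return self.assignments[name][0]

    def r_for(self, name: str) -> float:
        return self.assignments[name][1]


def _window_starts(n_samples: int, wlen: int, step: int) -> np.ndarray:
    if wlen > n_samples:
        raise ValueError("window longer than recording")
    return np.arange(0, n_samples - wlen + 1, step)


def compute_power_envelopes(act: SourceActivity, window: float = 1.0,
                            step: float = 1.0) -> PowerEnvelope:
    """Mean squared moment (summed over orientations) per source and window."""
    wlen = int(round(window * act.fs))
    stp = int(round(step * act.fs))
    if wlen < 2:
        raise ValueError("window must span at least 2 samples")
    if act.source_indices is not None:
        raise ValueError("power envelopes need full-grid activity; "
                         "use the active-subset moments directly")
    starts = _window_starts(act.n_samples, wlen, stp)
    p2 = (act.moments**2).sum(axis=1)    # (S, T)
    power = np.empty((act.moments.shape[0], starts.size))
    for w, s in enumerate(starts):
        power[:, w] = p2[:, s:s + wlen].mean(axis=1)
    return PowerEnvelope(power=power, window=window, step=step, fs=act.fs)


def compute_power_envelopes_from_operator(rec: Recording, op: InverseOperator,
                                          window: float = 1.0,
                                          step: float = 1.0) -> PowerEnvelope:
    """Streaming envelope computation: apply the kernel window by window.

    Equivalent to apply_inverse followed by compute_power_envelopes but never
    materializes the full source time series.
    """
    eeg = rec.data[rec.eeg_indices]
    if eeg.shape[0] != op.n_channels:
        raise ValueError("channel count does not match operator")
    wlen = int(round(window * rec.fs))
    stp = int(round(step * rec.fs))
    if wlen < 2:
        raise ValueError("window must span at least 2 samples")
    starts = _window_starts(rec.n_samples, wlen, stp)
    K = op.kernel2d
    power = np.empty((op.n_sources, starts.size))
    for w, s in enumerate(starts):
        m = K @ eeg[:, s:s + wlen]
        power[:, w] = (m.reshape(op.n_sources, 3, wlen)**2).sum(axis=1).mean(axis=1)
    return PowerEnvelope(power=power, window=window, step=step, fs=rec.fs)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / np.maximum(sd, 1e-300)


def estimate_num_ics_mdl(env: PowerEnvelope, max_order: int | None = None) -> int:
    """Minimum-description-length model order from envelope eigenvalues.

    Classical formulation on the eigenvalues of the covariance of the
    standardized envelope matrix, with effective sample size equal to the
    number of windows.
    """
    if env.n_windows < 10:
        raise ValueError("need at least 10 windows for order selection")
    X = _standardize_rows(env.power)
    # eigenvalues of the windows x windows covariance (sources as samples)
    sv = np.linalg.svd(X / np.sqrt(X.shape[0]), compute_uv=False)
    lam = sv**2
    p = min(env.n_windows, env.n_sources)
    lam = lam[:p]
    if lam[0] <= 0 or not np.all(np.isfinite(lam)):
        raise ValueError("degenerate envelope covariance")
    lam = np.maximum(lam, lam[0] * 1e-12)
    N = env.n_windows
    kmax = p - 2 if max_order is None else min(max_order, p - 2)
    mdl = np.empty(kmax + 1)
    for k in range(kmax + 1):
        tail = lam[k:]
        log_g = np.mean(np.log(tail))
        log_a = np.log(np.mean(tail))
        mdl[k] = -N * (p - k) * (log_g - log_a) + 0.5 * k * (2 * p - k) * np.log(N)
    return max(int(np.argmin(mdl)), 1)


def _negentropy(maps: np.ndarray) -> float:
    """Sum of logcosh negentropy proxies over unit-variance components."""
    z = _standardize_rows(maps.T)
    e_gauss = 0.3745672075248852  # E[log cosh N(0,1)]
    return float(np.sum((np.mean(np.log(np.cosh(z)), axis=1) - e_gauss)**2))


def run_spatial_ica(env: PowerEnvelope, k: int, n_runs: int = 10,
                    seed: int = 0, normalize: str = "center") -> ICResult:
    """Deflation FastICA over the source dimension, best of ``n_runs``.

    Each source's envelope is mean-centered (``normalize="center"``, the
    default: centering is the strongest per-source normalization that leaves
    the spatial mixture model exact; full per-source variance scaling,
    available as ``normalize="zscore"``, rescales every sample of the
    spatial ICA problem by a signal-dependent factor and degrades map
    recovery).  The data are reduced to ``k`` principal components and
    FastICA with tanh contrast is restarted ``n_runs`` times; the run with
    the highest summed negentropy is kept.  Maps are unit-variance with
    non-negative skewness.
    """
    bound = min(env.n_sources, env.n_windows)
    if not (1 <= k <= bound):
        raise ValueError(f"k must be in [1, {bound}]")
    if normalize == "center":
        X = env.power - env.power.mean(axis=1, keepdims=True)
    elif normalize == "zscore":
        X = _standardize_rows(env.power)
    else:
        raise ValueError("normalize must be 'center' or 'zscore'")
    objectives = np.full(n_runs, -np.inf)
    results = []
    any_converged = False
    for run in range(n_runs):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(n_components=k, algorithm="deflation", fun="logcosh",
                          whiten="unit-variance", max_iter=500, tol=1e-4,
                          random_state=seed * 1009 + run)
            maps = ica.fit_transform(X)       # (S, k)
            mixing = ica.mixing_              # (W, k)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
        any_converged = any_converged or converged
        objectives[run] = _negentropy(maps) if converged else -np.inf
        results.append((maps, mixing, converged))
    if not any_converged:
        raise RuntimeError(
            f"no FastICA run converged in {n_runs} restarts "
            f"(objectives: {objectives.tolist()})")
    best = int(np.argmax(objectives))
    maps, mixing, _ = results[best]
    sd = maps.std(axis=0)
    sd = np.maximum(sd, 1e-300)
    maps = (maps - maps.mean(axis=0)) / sd
    timecourses = (mixing * sd).T             # (k, W)
    sign = np.where(stats.skew(maps, axis=0) < 0, -1.0, 1.0)
    maps = maps * sign
    timecourses = timecourses * sign[:, None]
    return ICResult(maps=maps, timecourses=timecourses, k=k,
                    objectives=objectives, best_run=best)


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlations: (a_cols, b_cols)."""
    az = _standardize_rows(a.T)
    bz = _standardize_rows(b.T)
    return az @ bz.T / a.shape[0]


def match_templates(ics: ICResult, templates: TemplateSet) -> RSNAssignment:
    """Greedy no-reuse assignment of ICs to templates by Pearson correlation.

    Correlations are computed between absolute, z-scored maps.  The globally
    largest remaining (template, IC) pair is assigned and both removed from
    their pools; an IC is never associated with two templates.
    """
    if ics.maps.shape[0] != templates.maps.shape[0]:
        raise ValueError("templates and IC maps live on different source spaces")
    n_t = templates.maps.shape[1]
    n_i = ics.k
    if n_i < n_t:
        warnings.warn(f"only {n_i} ICs for {n_t} templates; partial assignment",
                      stacklevel=2)
    corr = _pearson_matrix(np.abs(templates.maps), np.abs(ics.maps))  # (T, I)
    work = corr.copy()
    assignments = {}
    for _ in range(min(n_t, n_i)):
        t, i = np.unravel_index(np.nanargmax(work), work.shape)
        assignments[templates.names[t]] = (int(i), float(corr[t, i]))
        work[t, :] = -np.inf
        work[:, i] = -np.inf
    used = {v[0] for v in assignments.values()}
    unmatched = [i for i in range(n_i) if i not in used]
    return RSNAssignment(assignments=assignments, unmatched_ics=unmatched)
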