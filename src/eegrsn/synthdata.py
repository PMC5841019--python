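"""Synthetic resting-state recordings with planted ground-truth networks.

Emulates 256-channel, 1000 Hz, 5-min resting recordings containing k
spatially disjoint cortical networks.  Within a network, every source emits
a band-limited carrier (default alpha, 8-13 Hz) whose slow positive
amplitude envelope is shared across the network up to calibrated per-source
jitter, so that envelopes co-fluctuate within networks and are independent
across networks -- exactly the statistical structure the envelope-ICA
detection stage exploits.  Ocular and myogenic artifacts and white sensor
noise are added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import brentq

from .containers import AUX_KINDS, EEG, Montage, NetworkMap, Recording, SourceActivity
from .forward import Leadfield, SourceSpace
from .geometry import fibonacci_cap_points

# Auxiliary electrode sites in head coordinates, as fractions of the scalp
# radius (vEOG above the right eye, hEOG at the outer canthus, EMG on the
# neck).  Fixed conventional positions so artifact topographies are
# reproducible.
_AUX_POSITIONS = {
    "hEOG": (0.80, 0.55, -0.15),
    "vEOG": (0.25, 0.90, -0.10),
    "EMG": (0.00, -0.85, -0.50),
}


@dataclass
class NetworkSpec:
    """Ground-truth network structure for the simulator."""

    regions: list            # list of 1D index arrays, pairwise disjoint
    rho_in: float = 0.9      # target within-network envelope correlation
    rho_out: float = 0.0     # target between-network envelope correlation
    carrier_band: tuple = (8.0, 13.0)   # Hz
    envelope_cutoff: float = 1.0        # Hz, low-pass of the slow envelope
    amplitude: float = 20.0             # nA*m RMS per in-network source
    background_fraction: float = 0.5    # background amplitude relative to networks
    n_background: int = 200             # diffuse independent background sources

    def __post_init__(self) -> None:
        self.regions = [np.asarray(r, dtype=int) for r in self.regions]
        if not (0.0 < self.rho_in <= 1.0):
            raise ValueError("rho_in must be in (0, 1]")
        if self.rho_out < 0 or self.rho_out >= self.rho_in:
            raise ValueError("need 0 <= rho_out < rho_in")
        all_idx = np.concatenate(self.regions) if self.regions else np.array([], int)
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("network regions must be pairwise disjoint")

    @property
    def k(self) -> int:
        return len(self.regions)


@dataclass
class NoiseSpec:
    """Sensor noise and biological artifact parameters."""

    sensor_noise_sd: float = 1.0      # uV; ignored when sensor_snr is set
    sensor_snr: float | None = 4.0    # variance(signal)/variance(noise) at sensors
    blink_rate: float = 12.0          # events/min
    blink_amplitude: float = 150.0    # uV at the vEOG site
    blink_decay: float = 0.05         # m, topography decay constant
    emg_rate: float = 5.0             # bursts/min
    emg_band: tuple = (30.0, 80.0)    # Hz
    emg_amplitude: float = 20.0       # uV at the EMG site
    emg_decay: float = 0.04           # m
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensor_noise_sd", "blink_rate", "blink_amplitude",
                     "blink_decay", "emg_rate", "emg_amplitude", "emg_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_montage(n_electrodes: int, head_radius: float = 0.1,
                 seed: int = 0) -> Montage:
    """Quasi-uniform EEG montage on the upper scalp plus hEOG/vEOG/EMG.

    Deterministic golden-angle spiral placement; the seed only rotates the
    spiral about the vertical axis.
    """
    if n_electrodes < 8:
        raise ValueError("need at least 8 electrodes")
    offset = 0.1 * int(seed)
    eeg = fibonacci_cap_points(n_electrodes, head_radius, z_min_frac=0.0,
                               azimuth_offset=offset)
    labels = [f"E{i + 1:03d}" for i in range(n_electrodes)] + list(AUX_KINDS)
    kinds = [EEG] * n_electrodes + list(AUX_KINDS)
    positions = np.vstack([eeg] + [head_radius * np.asarray(_AUX_POSITIONS[k])[None, :]
                                   for k in AUX_KINDS])
    return Montage(labels=labels, positions=positions, kinds=kinds)


def _abs_normal_corr(rho_g: float) -> float:
    """Correlation of |X|,|Y| for standard bivariate normals with corr rho_g."""
    num = np.sqrt(1.0 - rho_g**2) + rho_g * np.arcsin(rho_g) - 1.0
    return (2.0 / np.pi) * num / (1.0 - 2.0 / np.pi)


def _gaussian_corr_for_envelope(rho_target: float) -> float:
    """Invert the |N| correlation so envelopes hit the requested correlation."""
    if rho_target <= 0:
        return 0.0
    if rho_target >= _abs_normal_corr(1.0 - 1e-12):
        return 1.0
    return brentq(lambda r: _abs_normal_corr(r) - rho_target, 0.0, 1.0 - 1e-12,
                  xtol=1e-10)


def _slow_gaussian(rng: np.random.Generator, n: int, fs: float,
                   cutoff: float, size: int = 1) -> np.ndarray:
    """Low-pass filtered unit-variance Gaussian noise, shape (size, n)."""
    w = rng.standard_normal((size, n))
    sos = sps.butter(2, cutoff / (fs / 2.0), btype="low", output="sos")
    z = sps.sosfiltfilt(sos, w, axis=1)
    z /= z.std(axis=1, keepdims=True) + 1e-300
    return z


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple, size: int = 1) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, shape (size, n)."""
    lo = band[0] / (fs / 2.0)
    hi = min(band[1], 0.45 * fs) / (fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="band", output="sos")
    c = sps.sosfiltfilt(sos, rng.standard_normal((size, n)), axis=1)
    c /= c.std(axis=1, keepdims=True) + 1e-300
    return c


def default_network_spec(space: SourceSpace, k: int = 4, seed: int = 0,
                         region_radius: float = 0.035, **kwargs) -> NetworkSpec:
    """Plant k well-separated network regions of resting-state-network extent.

    Region centers are chosen by farthest-point sampling among superficial
    sources in the upper half of the head (z >= 0), i.e. cortex actually
    covered by the electrode montage; each region is the set of sources
    within ``region_radius`` of its center, with ties going to the nearest
    center so regions stay disjoint.  The default radius plants territories
    of a few percent of the gray-matter grid each, the scale of real
    resting-state networks.
    """
    rng = np.random.default_rng(seed)
    pos = space.positions
    r = np.linalg.norm(pos, axis=1)
    shallow = np.where((r >= space.inner_radius
                        + 0.7 * (space.outer_radius - space.inner_radius))
                       & (pos[:, 2] >= 0.0))[0]
    if shallow.size < k:
        raise ValueError("not enough superficial sources for requested k")
    cand = pos[shallow]
    first = shallow[rng.integers(shallow.size)]
    centers = [first]
    for _ in range(k - 1):
        d = np.min(np.linalg.norm(cand[:, None, :] - pos[centers][None, :, :],
                                  axis=2), axis=1)
        centers.append(shallow[int(np.argmax(d))])
    cpos = pos[centers]
    dist = np.linalg.norm(pos[:, None, :] - cpos[None, :, :], axis=2)  # (S, k)
    nearest = np.argmin(dist, axis=1)
    regions = []
    for j in range(k):
        members = np.where((dist[:, j] <= region_radius) & (nearest == j))[0]
        regions.append(members)
    return NetworkSpec(regions=regions, **kwargs)


def simulate_source_networks(spec: NetworkSpec, space: SourceSpace,
                             duration: float, fs: float, seed: int = 0,
                             return_envelopes: bool = False):
    """Simulate source activity with planted envelope-correlated networks.

    Returns (SourceActivity, list of binary NetworkMap ground truths); with
    ``return_envelopes`` also the per-active-source amplitude envelopes.
    The per-source Gaussian mixing weight is calibrated so the Pearson
    correlation of the positive envelopes themselves (not the underlying
    Gaussians) matches rho_in within and rho_out between networks.
    """
    for reg in spec.regions:
        if reg.size and reg.max() >= space.n_sources:
            raise ValueError("region index out of range for source space")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))

    rho_in_g = _gaussian_corr_for_envelope(spec.rho_in)
    rho_out_g = _gaussian_corr_for_envelope(spec.rho_out)
    a2 = rho_out_g                      # shared-across-all weight
    b2 = rho_in_g - rho_out_g           # network-specific weight
    c2 = 1.0 - rho_in_g                 # per-source jitter weight

    network_idx = spec.regions
    net_sizes = [r.size for r in network_idx]
    active = list(np.concatenate(network_idx)) if spec.k else []

    # diffuse independent background on a random subsample of the grid
    in_net = np.zeros(space.n_sources, dtype=bool)
    for reg in network_idx:
        in_net[reg] = True
    bg_pool = np.where(~in_net)[0]
    n_bg = min(spec.n_background, bg_pool.size)
    bg_idx = rng.choice(bg_pool, size=n_bg, replace=False) if n_bg else np.array([], int)
    all_idx = np.array(active + list(bg_idx), dtype=int)

    n_active = all_idx.size
    moments = np.zeros((n_active, 3, n), dtype=float)
    envelopes = np.zeros((n_active, n), dtype=float) if return_envelopes else None
    orientations = rng.standard_normal((n_active, 3))
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)

    g_global = _slow_gaussian(rng, n, fs, spec.envelope_cutoff)[0]
    row = 0
    for j, reg in enumerate(network_idx):
        g_net = _slow_gaussian(rng, n, fs, spec.envelope_cutoff)[0]
        base = np.sqrt(a2) * g_global + np.sqrt(b2) * g_net
        for _ in range(reg.size):
            jit = _slow_gaussian(rng, n, fs, spec.envelope_cutoff)[0]
            env = np.abs(base + np.sqrt(c2) * jit)
            carrier = _band_noise(rng, n, fs, spec.carrier_band)[0]
            sig = env * carrier
            rms = sig.std() + 1e-300
            sig *= spec.amplitude / rms
            moments[row] = orientations[row][:, None] * sig[None, :]
            if return_envelopes is not False and envelopes is not None:
                envelopes[row] = env
            row += 1
    bg_amp = spec.background_fraction * spec.amplitude
    for _ in range(n_bg):
        env = np.abs(_slow_gaussian(rng, n, fs, spec.envelope_cutoff)[0])
        carrier = _band_noise(rng, n, fs, spec.carrier_band)[0]
        sig = env * carrier
        sig *= bg_amp / (sig.std() + 1e-300)
        moments[row] = orientations[row][:, None] * sig[None, :]
        if envelopes is not None:
            envelopes[row] = env
        row += 1

    act = SourceActivity(moments=moments, fs=fs, n_sources=space.n_sources,
                         source_indices=all_idx)
    maps = []
    for j, reg in enumerate(network_idx):
        v = np.zeros(space.n_sources)
        v[reg] = 1.0
        maps.append(NetworkMap(values=v, name=f"NET{j + 1}"))
    if return_envelopes:
        return act, maps, envelopes
    return act, maps


def project_to_sensors(activity: SourceActivity, leadfield: Leadfield,
                       noise: NoiseSpec, montage: Montage | None = None,
                       chunk: int = 20000) -> Recording:
    """Project source moments through the leadfield and add sensor noise.

    sensor data = leadfield . activity + white noise; auxiliary channels
    carry noise only (their artifact content is added by inject_artifacts).
    If ``noise.sensor_snr`` is set, the noise sd is chosen so that the mean
    EEG-channel signal variance over noise variance equals it.
    """
    if activity.n_sources != leadfield.n_sources:
        raise ValueError("activity source count does not match leadfield")
    n_eeg = leadfield.n_channels
    n = activity.n_samples
    idx = (activity.source_indices if activity.source_indices is not None
           else np.arange(activity.n_sources))
    G = leadfield.gain[:, idx, :].reshape(n_eeg, -1)      # (C, 3*active)
    M = activity.moments.reshape(-1, n)                   # (3*active, T)
    sig = np.empty((n_eeg, n))
    for t0 in range(0, n, chunk):
        sig[:, t0:t0 + chunk] = G @ M[:, t0:t0 + chunk]

    rng = np.random.default_rng(noise.seed)
    if noise.sensor_snr is not None:
        sig_var = sig.var(axis=1).mean()
        sd = np.sqrt(sig_var / noise.sensor_snr) if sig_var > 0 else 0.0
    else:
        sd = noise.sensor_noise_sd
    if montage is not None:
        labels = list(montage.labels)
        kinds = list(montage.kinds)
        eeg_rows = montage.eeg_indices
        data = np.zeros((len(labels), n))
        data[eeg_rows] = sig
    else:
        labels = list(leadfield.labels) + list(AUX_KINDS)
        kinds = [EEG] * n_eeg + list(AUX_KINDS)
        data = np.vstack([sig, np.zeros((3, n))])
    if sd > 0:
        data = data + rng.normal(0.0, sd, size=data.shape)
    return Recording(data=data, fs=activity.fs, labels=labels, kinds=kinds)


def _blink_waveform(fs: float, width: float = 0.4) -> np.ndarray:
    """Monophasic 400-ms raised-cosine pulse (unit peak)."""
    t = np.arange(int(round(width * fs)))
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / max(len(t) - 1, 1)))


def inject_artifacts(rec: Recording, montage: Montage,
                     noise: NoiseSpec) -> Recording:
    """Add blink transients and band-limited EMG bursts.

    Blinks: stereotyped raised-cosine pulses, full amplitude on the vEOG
    channel, decaying over EEG channels with distance from the vEOG site.
    EMG: band-limited bursts on the EMG channel, decaying over EEG channels
    with distance from the EMG site.  Deterministic given ``noise.seed``.
    """
    for kind in AUX_KINDS:
        if kind not in rec.kinds:
            raise ValueError(f"recording lacks auxiliary channel {kind}")
    out = rec.copy()
    rng = np.random.default_rng(noise.seed + 1)
    n = rec.n_samples
    fs = rec.fs
    minutes = rec.duration / 60.0
    eeg_rows = rec.eeg_indices
    eeg_pos = montage.positions[montage.eeg_indices]
    if eeg_rows.size != eeg_pos.shape[0]:
        raise ValueError("montage EEG count does not match recording")

    if noise.blink_rate > 0 and noise.blink_amplitude > 0:
        v_row = rec.aux_index("vEOG")
        v_pos = montage.positions[montage.aux_index("vEOG")]
        w = _blink_waveform(fs)
        decay = np.exp(-np.linalg.norm(eeg_pos - v_pos, axis=1) / noise.blink_decay)
        n_events = rng.poisson(noise.blink_rate * minutes)
        starts = np.sort(rng.integers(0, max(n - len(w), 1), size=n_events))
        for s in starts:
            seg = slice(s, s + len(w))
            width = out.data[v_row, seg].shape[0]
            out.data[v_row, seg] += noise.blink_amplitude * w[:width]
            out.data[np.ix_(eeg_rows, range(s, s + width))] += (
                noise.blink_amplitude * decay[:, None] * w[None, :width])

    if noise.emg_rate > 0 and noise.emg_amplitude > 0:
        m_row = rec.aux_index("EMG")
        m_pos = montage.positions[montage.aux_index("EMG")]
        decay = np.exp(-np.linalg.norm(eeg_pos - m_pos, axis=1) / noise.emg_decay)
        n_events = rng.poisson(noise.emg_rate * minutes)
        for _ in range(n_events):
            dur = rng.uniform(0.3, 0.8)
            ns = int(round(dur * fs))
            s = int(rng.integers(0, max(n - ns, 1)))
            burst = _band_noise(rng, ns, fs, noise.emg_band)[0]
            burst *= sps.windows.tukey(ns, 0.25) * noise.emg_amplitude
            out.data[m_row, s:s + ns] += burst
            out.data[np.ix_(eeg_rows, range(s, s + ns))] += (
                decay[:, None] * burst[None, :])
    return out


def simulate_subject(space: SourceSpace, leadfield: Leadfield,
                     montage: Montage, seed: int = 0, k: int = 4,
                     duration: float = 300.0, fs: float = 1000.0,
                     network_kwargs: dict | None = None,
                     noise: NoiseSpec | None = None,
                     artifacts: bool = True):
    """One synthetic resting subject: recording + ground-truth network maps.

    Study conditions default to a 256-channel 5-min recording at 1000 Hz
    with 4 planted networks (pass smaller fs/duration for quick runs).
    """
    spec = default_network_spec(space, k=k, seed=seed,
                                **(network_kwargs or {}))
    act, maps = simulate_source_networks(spec, space, duration, fs, seed=seed + 1)
    ns = noise if noise is not None else NoiseSpec(seed=seed + 2)
    rec = project_to_sensors(act, leadfield, ns, montage=montage)
    if artifacts:
        rec = inject_artifacts(rec, montage, ns)
    return rec, maps, spec
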