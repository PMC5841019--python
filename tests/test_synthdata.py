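"""Montage construction, network simulation, projection, artifacts."""

import numpy as np
import pytest
from scipy import signal as sps

from eegrsn.containers import SourceActivity
from eegrsn.forward import SourceSpace, build_source_grid, compute_leadfield
from eegrsn.geometry import fibonacci_cap_points, pairwise_min_great_circle
from eegrsn.synthdata import (NetworkSpec, NoiseSpec, default_network_spec,
                              inject_artifacts, make_montage,
                              project_to_sensors, simulate_source_networks)

# --------------------------------------------------------------------------
# montage


def test_montage_radii_and_aux_channels():
    mont = make_montage(256, head_radius=0.092)
    eeg = mont.eeg_positions
    assert eeg.shape == (256, 3)
    assert np.abs(np.linalg.norm(eeg, axis=1) - 0.092).max() < 1e-9
    assert np.all(eeg[:, 2] >= -0.02 * 0.092)
    assert [mont.kinds[i] for i in mont.aux_indices] == ["hEOG", "vEOG", "EMG"]
    assert len(set(mont.labels)) == mont.n_channels


def test_montage_deterministic_per_seed():
    a = make_montage(32, seed=7)
    b = make_montage(32, seed=7)
    c = make_montage(32, seed=8)
    assert np.array_equal(a.positions, b.positions)
    assert not np.array_equal(a.positions, c.positions)


def test_montage_rejects_too_few_electrodes():
    with pytest.raises(ValueError):
        make_montage(7)


def test_montage_packing_beats_random_placement_oracle():
    """Spiral min pairwise great-circle distance vs best-of-1000 random."""
    n, radius = 64, 0.1
    mont = make_montage(n, head_radius=radius)
    ours = pairwise_min_great_circle(mont.eeg_positions)

    rng = np.random.default_rng(0)
    best = 0.0
    for _ in range(1000):
        z = rng.uniform(0, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        rho = np.sqrt(1 - z**2)
        pts = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
        best = max(best, pairwise_min_great_circle(pts))
    assert ours >= 0.75 * best


# --------------------------------------------------------------------------
# source network simulation


@pytest.fixture(scope="module")
def ribbon(head4):
    return build_source_grid(head4, spacing=0.012)


def test_ground_truth_maps_disjoint(ribbon):
    spec = default_network_spec(ribbon, k=4, seed=0)
    act, maps = simulate_source_networks(spec, ribbon, duration=4.0, fs=200.0)
    assert len(maps) == 4
    stack = np.column_stack([m.values for m in maps])
    assert np.all(stack.sum(axis=1) <= 1.0)   # no source in two networks
    for i in range(4):
        for j in range(i + 1, 4):
            assert np.dot(stack[:, i], stack[:, j]) == 0.0


def test_envelope_correlations_hit_targets(ribbon):
    """Empirical within/between-network envelope correlations over 5 min."""
    spec = default_network_spec(ribbon, k=3, seed=1, rho_in=0.9, rho_out=0.0)
    act, maps, env = simulate_source_networks(spec, ribbon, duration=300.0,
                                              fs=100.0, seed=2,
                                              return_envelopes=True)
    sizes = [r.size for r in spec.regions]
    bounds = np.cumsum([0] + sizes)
    C = np.corrcoef(env[:bounds[-1]])
    within, between = [], []
    for a in range(3):
        sa = slice(bounds[a], bounds[a + 1])
        blk = C[sa, sa]
        within.extend(blk[np.triu_indices_from(blk, 1)])
        for b in range(a + 1, 3):
            between.extend(C[sa, slice(bounds[b], bounds[b + 1])].ravel())
    assert np.mean(within) >= 0.8
    assert abs(np.mean(between)) <= 0.2


def test_background_envelopes_uncorrelated_with_networks(ribbon):
    spec = default_network_spec(ribbon, k=2, seed=3, n_background=50)
    act, maps, env = simulate_source_networks(spec, ribbon, duration=300.0,
                                              fs=100.0, seed=4,
                                              return_envelopes=True)
    n_net = sum(r.size for r in spec.regions)
    net_env = np.vstack([env[:spec.regions[0].size].mean(axis=0),
                         env[spec.regions[0].size:n_net].mean(axis=0)])
    bg = env[n_net:]
    r = np.corrcoef(np.vstack([net_env, bg]))[2:, :2]
    assert np.abs(r).mean() < 0.1


def test_zero_amplitude_gives_zero_activity(ribbon):
    spec = default_network_spec(ribbon, k=2, seed=0, amplitude=0.0,
                                background_fraction=0.0)
    act, _ = simulate_source_networks(spec, ribbon, duration=2.0, fs=200.0)
    assert np.all(act.moments == 0.0)


def test_overlapping_regions_rejected():
    with pytest.raises(ValueError):
        NetworkSpec(regions=[np.array([1, 2, 3]), np.array([3, 4])])


def test_region_index_out_of_range_rejected(ribbon):
    spec = NetworkSpec(regions=[np.array([ribbon.n_sources + 5])])
    with pytest.raises(ValueError):
        simulate_source_networks(spec, ribbon, duration=1.0, fs=100.0)


def test_simulation_deterministic(ribbon):
    spec = default_network_spec(ribbon, k=2, seed=0)
    a, _ = simulate_source_networks(spec, ribbon, duration=2.0, fs=200.0, seed=9)
    b, _ = simulate_source_networks(spec, ribbon, duration=2.0, fs=200.0, seed=9)
    assert np.array_equal(a.moments, b.moments)


# --------------------------------------------------------------------------
# projection


@pytest.fixture(scope="module")
def proj_setup(head4, ribbon):
    mont = make_montage(32, head_radius=head4.scalp_radius)
    lf = compute_leadfield(mont, head4, ribbon)
    spec = default_network_spec(ribbon, k=2, seed=0)
    act, _ = simulate_source_networks(spec, ribbon, duration=4.0, fs=200.0, seed=1)
    return mont, lf, act


def test_projection_linearity(proj_setup):
    mont, lf, act = proj_setup
    quiet = NoiseSpec(sensor_snr=None, sensor_noise_sd=0.0, seed=0)
    r1 = project_to_sensors(act, lf, quiet, montage=mont)
    r2 = project_to_sensors(act.scaled(2.5), lf, quiet, montage=mont)
    assert np.allclose(r2.data, 2.5 * r1.data, atol=1e-10)
    zero = SourceActivity(moments=np.zeros_like(act.moments), fs=act.fs,
                          n_sources=act.n_sources,
                          source_indices=act.source_indices)
    r0 = project_to_sensors(zero, lf, quiet, montage=mont)
    assert np.all(r0.data == 0.0)


def test_projection_hits_requested_snr(proj_setup):
    mont, lf, act = proj_setup
    rec_clean = project_to_sensors(
        act, lf, NoiseSpec(sensor_snr=None, sensor_noise_sd=0.0), montage=mont)
    rec = project_to_sensors(act, lf, NoiseSpec(sensor_snr=4.0, seed=3),
                             montage=mont)
    eeg = mont.eeg_indices
    noise = rec.data[eeg] - rec_clean.data[eeg]
    ratio = rec_clean.data[eeg].var(axis=1).mean() / noise.var(axis=1).mean()
    assert abs(ratio - 4.0) / 4.0 < 0.1


def test_projection_dimension_mismatch(proj_setup):
    mont, lf, act = proj_setup
    bad = SourceActivity(moments=act.moments, fs=act.fs,
                         n_sources=act.n_sources + 7,
                         source_indices=act.source_indices)
    with pytest.raises(ValueError):
        project_to_sensors(bad, lf, NoiseSpec())


# --------------------------------------------------------------------------
# artifacts


@pytest.fixture(scope="module")
def quiet_recording(proj_setup):
    mont, lf, act = proj_setup
    spec = NetworkSpec(regions=[np.array([0, 1])], amplitude=0.0,
                       background_fraction=0.0, n_background=0)
    silent, _ = simulate_source_networks(spec, SourceSpace(
        positions=np.zeros((act.n_sources, 3)), spacing=0.006,
        inner_radius=0, outer_radius=1), duration=300.0, fs=200.0)
    rec = project_to_sensors(silent, lf,
                             NoiseSpec(sensor_snr=None, sensor_noise_sd=1.0,
                                       seed=5), montage=mont)
    return mont, rec


def test_artifacts_zero_rates_are_noop(quiet_recording):
    mont, rec = quiet_recording
    out = inject_artifacts(rec, mont, NoiseSpec(blink_rate=0.0, emg_rate=0.0))
    assert np.array_equal(out.data, rec.data)


def test_blink_count_matches_rate(quiet_recording):
    """12 blinks/min over 5 min: ~60 vEOG peaks above 5x background sd."""
    mont, rec = quiet_recording
    ns = NoiseSpec(blink_rate=12.0, emg_rate=0.0, seed=11)
    out = inject_artifacts(rec, mont, ns)
    v = out.data[rec.aux_index("vEOG")]
    bg_sd = rec.data[rec.aux_index("vEOG")].std()
    peaks, _ = sps.find_peaks(v, height=5 * bg_sd,
                              distance=int(0.3 * rec.fs))
    lam = 60.0
    assert abs(len(peaks) - lam) <= 4 * np.sqrt(lam)   # Poisson-consistent


def test_emg_bursts_raise_high_band_power(quiet_recording):
    mont, rec = quiet_recording
    ns = NoiseSpec(blink_rate=0.0, emg_rate=10.0, seed=12)
    out = inject_artifacts(rec, mont, ns)
    emg_pos = mont.positions[mont.aux_index("EMG")]
    eeg = mont.eeg_indices
    d = np.linalg.norm(mont.positions[eeg] - emg_pos, axis=1)
    nearest = eeg[np.argmin(d)]

    def frac_above30(x):
        f, p = sps.welch(x, fs=rec.fs, nperseg=1024)
        return p[f > 30].sum() / p.sum()

    row = list(rec.labels).index(rec.labels[nearest])
    assert frac_above30(out.data[row]) > frac_above30(rec.data[row])


def test_artifacts_require_aux_channels(quiet_recording):
    mont, rec = quiet_recording
    eeg_only = rec.select_channels(list(rec.eeg_indices))
    with pytest.raises(ValueError):
        inject_artifacts(eeg_only, mont, NoiseSpec())


def test_artifacts_deterministic(quiet_recording):
    mont, rec = quiet_recording
    ns = NoiseSpec(seed=21)
    a = inject_artifacts(rec, mont, ns)
    b = inject_artifacts(rec, mont, ns)
    assert np.array_equal(a.data, b.data)


def test_fibonacci_cap_respects_zmin():
    pts = fibonacci_cap_points(100, 1.0, z_min_frac=0.2)
    assert pts[:, 2].min() >= 0.2 - 1e-12
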