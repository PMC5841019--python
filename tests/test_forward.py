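"""Volume conductor, source grid, leadfield and montage subsampling."""

import numpy as np
import pytest

from eegrsn.containers import Montage, Recording
from eegrsn.forward import (HeadModel, SourceSpace, build_source_grid,
                            compute_leadfield, export_leadfield,
                            headmodel_variants, import_leadfield,
                            shell_factors, standard_montage_positions,
                            subsample_montage)
from eegrsn.synthdata import make_montage

# --------------------------------------------------------------------------
# independent oracles


def closed_form_single_sphere(re, r0, q, R, sigma):
    """Analytically summed dipole potential on a homogeneous sphere (volts).

    Independent of the package's truncated-series path: the Legendre sums
    are evaluated in closed form via generating functions.
    """
    b = np.linalg.norm(r0)
    rehat = re / np.linalg.norm(re)
    if b < 1e-14:
        return 3.0 * (q @ rehat) / (4 * np.pi * sigma * R**2)
    r0hat = r0 / b
    x = b / R
    u = float(np.clip(rehat @ r0hat, -1, 1))
    g = np.sqrt(1 - 2 * x * u + x * x)
    h = 1 - x * u + g
    qr = q @ r0hat
    qt = q @ (rehat - u * r0hat)
    s_rad = 2 * (u - x) / g**3 + (1 / g - 1) / x
    s_tan = 2 / g**3 + (g + 1) / (g * h)
    return (qr * s_rad + qt * s_tan) / (4 * np.pi * sigma * R**2)


def oracle_shell_factors(head, n_max):
    """Per-degree shell factors by direct solve of the boundary conditions."""
    rho = np.asarray(head.radii) / head.radii[-1]
    sig = np.asarray(head.conductivities)
    m = rho.size
    out = np.zeros(n_max)
    for n in range(1, n_max + 1):
        # unknowns: A_1..A_m, B_2..B_m; the dipole's own coefficient B_1 = 1
        nunk = 2 * m - 1
        A = np.zeros((nunk, nunk))
        rhs = np.zeros(nunk)
        row = 0
        for j in range(m - 1):
            p = rho[j]
            # continuity of the potential
            A[row, j] += p**n
            A[row, j + 1] -= p**n
            A[row, m + j] -= p**-(n + 1)
            if j == 0:
                rhs[row] = -(p**-(n + 1))
            else:
                A[row, m + j - 1] += p**-(n + 1)
            row += 1
            # continuity of the radial current
            A[row, j] += sig[j] * n * p**(n - 1)
            A[row, j + 1] -= sig[j + 1] * n * p**(n - 1)
            A[row, m + j] += sig[j + 1] * (n + 1) * p**-(n + 2)
            if j == 0:
                rhs[row] = sig[j] * (n + 1) * p**-(n + 2)
            else:
                A[row, m + j - 1] -= sig[j] * (n + 1) * p**-(n + 2)
            row += 1
        A[row, m - 1] = n
        A[row, 2 * m - 2] = -(n + 1)
        sol = np.linalg.solve(A, rhs)
        out[n - 1] = sol[m - 1] + sol[2 * m - 2]
    return out


def brute_force_grid_count(radius_out, radius_in, spacing):
    count = 0
    m = int(np.floor(radius_out / spacing))
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                r = spacing * np.sqrt(i * i + j * j + k * k)
                if radius_in <= r <= radius_out:
                    count += 1
    return count


# --------------------------------------------------------------------------
# head model and source grid


def test_headmodel_validation():
    with pytest.raises(ValueError):
        HeadModel(radii=(0.09, 0.08), conductivities=(0.3, 0.3))
    with pytest.raises(ValueError):
        HeadModel(radii=(0.08, 0.09), conductivities=(0.3, -0.1))


def test_source_grid_matches_brute_force_enumeration(head4):
    space = build_source_grid(head4, spacing=0.006, shell_margin=0.006,
                              inner_fraction=0.55)
    expect = brute_force_grid_count(head4.brain_radius - 0.006,
                                    0.55 * head4.brain_radius, 0.006)
    assert space.n_sources == expect


def test_source_grid_lattice_properties(head4):
    space = build_source_grid(head4, spacing=0.006)
    r = space.radii()
    assert np.all(r < head4.brain_radius)
    assert np.all(r <= space.outer_radius + 1e-12)
    # nearest-neighbor distance equals the lattice spacing
    from scipy.spatial import cKDTree
    d, _ = cKDTree(space.positions).query(space.positions, k=2)
    assert abs(d[:, 1].min() - 0.006) < 1e-9


def test_empty_grid_raises(head4):
    with pytest.raises(ValueError):
        build_source_grid(head4, spacing=0.05, inner_fraction=0.99)


# --------------------------------------------------------------------------
# leadfield


@pytest.fixture(scope="module")
def random_sources():
    rng = np.random.default_rng(0)
    src = rng.standard_normal((40, 3))
    src /= np.linalg.norm(src, axis=1, keepdims=True)
    src *= rng.uniform(0.02, 0.072, size=(40, 1))
    return SourceSpace(positions=src, spacing=0.006, inner_radius=0.02,
                       outer_radius=0.072)


def test_equal_conductivities_match_single_sphere_closed_form(montage64,
                                                              random_sources):
    head = HeadModel(radii=(0.087, 0.092, 0.100),
                     conductivities=(0.33, 0.33, 0.33), label="homogeneous")
    lf = compute_leadfield(montage64, head, random_sources, truncation_order=60)
    epos = montage64.eeg_positions
    G = np.zeros_like(lf.gain)
    for s in range(random_sources.n_sources):
        for k in range(3):
            q = np.zeros(3)
            q[k] = 1e-9
            for e in range(epos.shape[0]):
                G[e, s, k] = closed_form_single_sphere(
                    epos[e], random_sources.positions[s], q, 0.100, 0.33) * 1e6
    G -= G.mean(axis=0, keepdims=True)
    rel = np.abs(lf.gain - G).max() / np.abs(G).max()
    assert rel < 1e-6


def test_three_shell_factors_match_order200_oracle():
    head = HeadModel(radii=(0.087, 0.092, 0.100),
                     conductivities=(0.33, 0.0042, 0.33), label="3-shell")
    F = shell_factors(head, 200)
    F_oracle = oracle_shell_factors(head, 200)
    assert np.abs(F - F_oracle).max() / np.abs(F_oracle).max() < 1e-10


def test_three_shell_leadfield_matches_high_order_series(montage64):
    """Truncated (order 60) gain vs an order-200 independently coded series."""
    head = HeadModel(radii=(0.087, 0.092, 0.100),
                     conductivities=(0.33, 0.0042, 0.33), label="3-shell")
    rng = np.random.default_rng(1)
    src = rng.standard_normal((30, 3))
    src /= np.linalg.norm(src, axis=1, keepdims=True)
    src *= rng.uniform(0.02, 0.07, size=(30, 1))
    space = SourceSpace(positions=src, spacing=0.006, inner_radius=0.02,
                        outer_radius=0.07)
    lf = compute_leadfield(montage64, head, space, truncation_order=60)

    # oracle: rebuild the potential source-by-source from the order-200
    # factors obtained by direct linear solve
    F = oracle_shell_factors(head, 200)
    R, sigma1 = 0.100, 0.33
    epos = montage64.eeg_positions
    rehat = epos / np.linalg.norm(epos, axis=1, keepdims=True)
    G = np.zeros_like(lf.gain)
    from numpy.polynomial import legendre
    for s in range(space.n_sources):
        r0 = space.positions[s]
        b = np.linalg.norm(r0)
        r0hat = r0 / b
        x = b / R
        for e in range(epos.shape[0]):
            u = float(np.clip(rehat[e] @ r0hat, -1, 1))
            s1 = s2 = 0.0
            pm, pc = 1.0, u          # P_0, P_1
            dm, dc = 0.0, 1.0        # P_0', P_1'
            xp = 1.0
            for n in range(1, 201):
                s1 += n * xp * F[n - 1] * pc
                s2 += xp * F[n - 1] * dc
                pn = ((2 * n + 1) * u * pc - n * pm) / (n + 1)
                dn = dm + (2 * n + 1) * pc
                pm, pc, dm, dc = pc, pn, dc, dn
                xp *= x
            for k in range(3):
                qr = r0hat[k]
                qt = rehat[e][k] - u * r0hat[k]
                G[e, s, k] = 1e-3 / (4 * np.pi * sigma1 * R**2) * (s1 * qr + s2 * qt)
    G -= G.mean(axis=0, keepdims=True)
    rel = np.abs(lf.gain - G).max() / np.abs(G).max()
    assert rel < 1e-4


def test_radial_dipole_axial_symmetry(head4):
    """Electrodes at equal polar angle see identical potential (z dipole)."""
    theta = np.deg2rad(40.0)
    phis = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    R = head4.scalp_radius
    pos = np.column_stack([R * np.sin(theta) * np.cos(phis),
                           R * np.sin(theta) * np.sin(phis),
                           R * np.cos(theta) * np.ones_like(phis)])
    mont = Montage(labels=[f"E{i}" for i in range(8)], positions=pos,
                   kinds=["EEG"] * 8)
    space = SourceSpace(positions=np.array([[0.0, 0.0, 0.05]]), spacing=0.006,
                        inner_radius=0.0, outer_radius=0.06)
    lf = compute_leadfield(mont, head4, space)
    v = lf.gain[:, 0, 2]   # radial (z) dipole
    assert np.abs(v - v[0]).max() < 1e-9 * max(np.abs(v[0]), 1e-30)


def test_leadfield_average_reference_and_linearity(leadfield64):
    # average reference: channel sums vanish
    sums = leadfield64.gain.sum(axis=0)
    assert np.abs(sums).max() < 1e-9 * np.abs(leadfield64.gain).max()
    # linearity in the dipole moment is structural: gain @ q
    rng = np.random.default_rng(2)
    q = rng.standard_normal(3)
    v1 = leadfield64.gain[:, 10, :] @ q
    v2 = sum(q[k] * leadfield64.gain[:, 10, k] for k in range(3))
    assert np.allclose(v1, v2, atol=1e-12)


def test_source_outside_innermost_shell_rejected(montage64, head4):
    space = SourceSpace(positions=np.array([[0.0, 0.0, 0.085]]), spacing=0.006,
                        inner_radius=0.0, outer_radius=0.09)
    with pytest.raises(ValueError):
        compute_leadfield(montage64, head4, space)


def test_low_truncation_order_warns(montage64, head4, small_space):
    with pytest.warns(UserWarning):
        compute_leadfield(montage64, head4, small_space, truncation_order=5)


def test_headmodel_variant_degradation_is_monotone(montage64, small_space):
    """Leadfield error vs the reference grows with model degradation."""
    variants = headmodel_variants()
    ref = compute_leadfield(montage64, variants["reference"], small_space)
    errs = []
    for name in ("merged", "averaged"):
        lf = compute_leadfield(montage64, variants[name], small_space)
        errs.append(np.linalg.norm(lf.gain - ref.gain) / np.linalg.norm(ref.gain))
    assert errs[0] < errs[1]
    assert errs[0] > 0


# --------------------------------------------------------------------------
# import / export


def test_leadfield_roundtrip(tmp_path, leadfield64, montage64, small_space, head4):
    path = tmp_path / "lf.h5"
    export_leadfield(path, leadfield64, small_space, head4)
    lf2 = import_leadfield(path, montage64, small_space)
    assert np.array_equal(lf2.gain, leadfield64.gain)
    assert lf2.labels == leadfield64.labels


def test_import_leadfield_rejects_wrong_channel_count(tmp_path, leadfield64,
                                                      small_space, head4):
    path = tmp_path / "lf.h5"
    export_leadfield(path, leadfield64, small_space, head4)
    montage32 = make_montage(32, head_radius=head4.scalp_radius)
    with pytest.raises(ValueError):
        import_leadfield(path, montage32, small_space)


def test_import_leadfield_rereferences(tmp_path, montage64, small_space):
    import h5py
    rng = np.random.default_rng(3)
    gain = rng.standard_normal((64, small_space.n_sources, 3))
    path = tmp_path / "raw_lf.h5"
    eeg_labels = [montage64.labels[i] for i in montage64.eeg_indices]
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=gain)
        f.create_dataset("labels", data=np.array(eeg_labels, dtype="S"))
    lf = import_leadfield(path, montage64, small_space)
    assert np.abs(lf.gain.sum(axis=0)).max() < 1e-9


# --------------------------------------------------------------------------
# montage subsampling


def _make_rec(montage, n=500, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(data=rng.standard_normal((montage.n_channels, n)),
                     fs=250.0, labels=list(montage.labels),
                     kinds=list(montage.kinds))


def test_subsample_full_is_identity():
    mont = make_montage(256)
    rec = _make_rec(mont)
    rec2, mont2 = subsample_montage(rec, mont, "full")
    assert rec2 is rec and mont2 is mont


@pytest.mark.parametrize("target", [32, 64, 128])
def test_subsample_matches_greedy_oracle(target):
    mont = make_montage(256)
    rec = _make_rec(mont)
    rec2, mont2 = subsample_montage(rec, mont, target)
    assert len(mont2.eeg_indices) == target
    # brute-force oracle: repeated global argmin with row/column removal
    eeg_pos = mont.eeg_positions
    radius = float(np.linalg.norm(eeg_pos, axis=1).mean())
    targets = standard_montage_positions(target, radius)
    dist = np.linalg.norm(targets[:, None, :] - eeg_pos[None, :, :], axis=2)
    work = dist.copy()
    chosen = {}
    for _ in range(target):
        t, e = np.unravel_index(np.argmin(work), work.shape)
        chosen[t] = e
        work[t, :] = np.inf
        work[:, e] = np.inf
    expect = [mont.labels[mont.eeg_indices[chosen[t]]] for t in sorted(chosen)]
    got = [mont2.labels[i] for i in mont2.eeg_indices]
    assert got == expect


def test_subsample_is_pure_selection():
    mont = make_montage(256)
    rec = _make_rec(mont)
    rec2, mont2 = subsample_montage(rec, mont, 32)
    for i, lab in enumerate(rec2.labels):
        src_row = rec.labels.index(lab)
        assert np.array_equal(rec2.data[i], rec.data[src_row])
    # aux channels are retained
    assert set(mont2.kinds) >= {"hEOG", "vEOG", "EMG"}


def test_subsample_unmatchable_position_raises():
    mont = make_montage(32)   # sparse montage cannot serve 128 targets
    rec = _make_rec(mont)
    with pytest.raises(ValueError):
        subsample_montage(rec, mont, 128)
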