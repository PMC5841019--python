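"""Volume conduction: concentric-shell head models, source grids, leadfields.

The volume conductor is an analytic m-shell concentric sphere.  The scalp
potential of a dipole inside the innermost shell is the classical Legendre
series: for a dipole of moment q (A*m) at radial distance b, electrode at
the scalp radius R with angle gamma to the dipole position,

    V = 1/(4 pi sigma_1 R^2) * sum_n  x^(n-1) F_n *
        [ n (q . r0_hat) P_n(u) + (q . (re_hat - u r0_hat)) P_n'(u) ]

with x = b/R, u = cos(gamma), and F_n a per-degree shell factor obtained by
propagating the interface conditions (continuity of potential and of radial
current) from the outer insulating boundary inward.  For a homogeneous
sphere F_n = (2n+1)/n.  The tangential term is written with P_n'(u) and the
un-normalized in-plane vector so that it is free of sin(gamma) singularities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .containers import Montage, Recording

DEFAULT_SPACING = 0.006  # 6-mm source grid


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell volume conductor.

    radii are strictly increasing (outermost = scalp surface), meters;
    conductivities in S/m, one per shell from innermost out.
    """

    radii: tuple
    conductivities: tuple
    label: str = "custom"

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        c = np.asarray(self.conductivities, dtype=float)
        if r.ndim != 1 or r.size < 1 or r.size != c.size:
            raise ValueError("radii and conductivities must be same-length 1D")
        if np.any(np.diff(r) <= 0):
            raise ValueError("shell radii must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return float(self.radii[0])

    @property
    def scalp_radius(self) -> float:
        return float(self.radii[-1])

    # Reference and degraded variants.  The reference is a 4-shell sphere
    # (brain / CSF / skull / scalp).  Simpler variants merge the CSF into the
    # brain compartment, or additionally assign the merged compartment the
    # average of the pooled conductivities -- emulating the fidelity ordering
    # of progressively coarser realistic head models.
    @classmethod
    def four_shell(cls) -> "HeadModel":
        return cls(radii=(0.080, 0.083, 0.092, 0.100),
                   conductivities=(0.33, 1.79, 0.0042, 0.33),
                   label="4-shell")

    @classmethod
    def three_shell(cls) -> "HeadModel":
        """CSF merged into the brain compartment (keeps brain conductivity)."""
        return cls(radii=(0.083, 0.092, 0.100),
                   conductivities=(0.33, 0.0042, 0.33),
                   label="3-shell")

    @classmethod
    def three_shell_averaged(cls) -> "HeadModel":
        """CSF merged into brain with pooled (averaged) conductivity."""
        return cls(radii=(0.083, 0.092, 0.100),
                   conductivities=((0.33 + 1.79) / 2.0, 0.0042, 0.33),
                   label="3-shell-avg")


def headmodel_variants() -> dict:
    """Head-model fidelity ladder used by the comparison experiments."""
    return {
        "reference": HeadModel.four_shell(),
        "merged": HeadModel.three_shell(),
        "averaged": HeadModel.three_shell_averaged(),
    }


@dataclass
class SourceSpace:
    """Regular cubic source lattice clipped to a spherical cortical ribbon."""

    positions: np.ndarray      # (n_sources, 3) meters
    spacing: float
    inner_radius: float
    outer_radius: float
    grid_ijk: np.ndarray = field(default=None)  # (n_sources, 3) int lattice indices
    vol_shape: tuple = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_sources, 3)")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)


def build_source_grid(head: HeadModel, spacing: float = DEFAULT_SPACING,
                      shell_margin: float = 0.006,
                      inner_fraction: float = 0.55) -> SourceSpace:
    """Axis-aligned cubic lattice clipped to a spherical ribbon.

    Keeps lattice points with inner_fraction*brain_radius <= |p| <=
    brain_radius - shell_margin, approximating a cortical gray-matter
    ribbon strictly inside the innermost shell.  Deterministic.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    outer = head.brain_radius - shell_margin
    inner = inner_fraction * head.brain_radius
    if outer <= 0 or outer <= inner:
        raise ValueError("margin/inner fraction leave no room for sources")
    m = int(np.floor(outer / spacing))
    axis = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pos = ijk * spacing
    r = np.linalg.norm(pos, axis=1)
    keep = (r >= inner) & (r <= outer)
    if not np.any(keep):
        raise ValueError("empty source grid for given spacing/margins")
    ijk = ijk[keep] + m  # shift to non-negative volume indices
    return SourceSpace(positions=pos[keep], spacing=spacing,
                       inner_radius=inner, outer_radius=outer,
                       grid_ijk=ijk, vol_shape=(2 * m + 1,) * 3)


@dataclass
class Leadfield:
    """Gain matrix: microvolts at each EEG channel per nA*m dipole moment."""

    gain: np.ndarray           # (n_channels, n_sources, 3)
    labels: list[str]          # EEG channel labels
    reference: str             # "raw" | "average"
    head_label: str = ""
    spacing: float = DEFAULT_SPACING
    truncation_order: int = 60

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValueError("gain must be (channels, sources, 3)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain must be finite")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """2D view (channels, sources*3) with orientation fastest."""
        return self.gain.reshape(self.n_channels, self.n_sources * 3)


def shell_factors(head: HeadModel, n_max: int) -> np.ndarray:
    """Per-degree shell factors F_n, n = 1..n_max.

    Starting from the outer insulating boundary with unit outgoing
    coefficient, the 2x2 interface conditions are propagated inward shell by
    shell; F_n is the ratio of the surface potential to the dipole's own
    r^-(n+1) coefficient in the innermost compartment.  Radii are normalized
    by the scalp radius for conditioning.  Homogeneous: F_n = (2n+1)/n.
    """
    n = np.arange(1, n_max + 1, dtype=float)
    rho = np.asarray(head.radii, dtype=float) / head.scalp_radius
    sig = np.asarray(head.conductivities, dtype=float)
    m = rho.size
    A = np.ones_like(n)
    B = n / (n + 1.0)
    for j in range(m - 2, -1, -1):      # interface between shells j and j+1
        p = rho[j]
        pn = p ** n
        pm = p ** -(n + 1.0)
        v = A * pn + B * pm
        d = n * A * pn / p - (n + 1.0) * B * pm / p
        w = (sig[j + 1] / sig[j]) * d * p
        A = ((n + 1.0) * v + w) / (2.0 * n + 1.0) / pn
        B = (n * v - w) / (2.0 * n + 1.0) / pm
    return (2.0 * n + 1.0) / (n + 1.0) / B


def compute_leadfield(montage: Montage, head: HeadModel, space: SourceSpace,
                      truncation_order: int = 60) -> Leadfield:
    """Analytic m-shell leadfield, average-referenced.

    Electrode positions are taken by direction and placed on the scalp
    sphere.  Output units: microvolts per nA*m.
    """
    import warnings
    if truncation_order < 10:
        warnings.warn("truncation_order < 10 gives a poor series approximation",
                      stacklevel=2)
    R = head.scalp_radius
    sigma1 = float(head.conductivities[0])
    elec = montage.eeg_positions
    enorm = np.linalg.norm(elec, axis=1)
    if np.any(enorm <= 0):
        raise ValueError("electrode at head center")
    re_hat = elec / enorm[:, None]

    src = space.positions
    b = np.linalg.norm(src, axis=1)
    if np.any(b >= head.brain_radius):
        raise ValueError("source outside innermost shell")
    r0_hat = np.zeros_like(src)
    nz = b > 1e-12
    r0_hat[nz] = src[nz] / b[nz, None]
    r0_hat[~nz] = [0.0, 0.0, 1.0]  # central dipole: any axis (limit is isotropic)

    F = shell_factors(head, truncation_order)
    x = b / R                                   # (S,)
    u = re_hat @ r0_hat.T                       # (C, S)

    # Accumulate S1 = sum n x^(n-1) F_n P_n(u), S2 = sum x^(n-1) F_n P_n'(u)
    S1 = np.zeros_like(u)
    S2 = np.zeros_like(u)
    P_nm1 = np.ones_like(u)    # P_0
    P_n = u.copy()             # P_1
    dP_nm1 = np.zeros_like(u)  # P_0'
    dP_n = np.ones_like(u)     # P_1'
    xp = np.ones_like(x)       # x^(n-1)
    for ni in range(1, truncation_order + 1):
        c = xp * F[ni - 1]
        S1 += (ni * c) * P_n
        S2 += c * dP_n
        # advance recurrences to degree ni+1
        P_np1 = ((2 * ni + 1) * u * P_n - ni * P_nm1) / (ni + 1)
        dP_np1 = dP_nm1 + (2 * ni + 1) * P_n
        P_nm1, P_n = P_n, P_np1
        dP_nm1, dP_n = dP_n, dP_np1
        xp = xp * x

    scale = 1e-3 / (4.0 * np.pi * sigma1 * R * R)  # volts/(A*m) -> uV/(nA*m)
    tang = re_hat[:, None, :] - u[:, :, None] * r0_hat[None, :, :]  # (C,S,3)
    gain = scale * (S1[:, :, None] * r0_hat[None, :, :] + S2[:, :, None] * tang)
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    eeg_labels = [montage.labels[i] for i in montage.eeg_indices]
    return Leadfield(gain=gain, labels=eeg_labels, reference="average",
                     head_label=head.label, spacing=space.spacing,
                     truncation_order=truncation_order)


def export_leadfield(path, lf: Leadfield, space: SourceSpace,
                     head: HeadModel | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("positions", data=space.positions)
        f.create_dataset("labels", data=np.array(lf.labels, dtype="S"))
        f.attrs["reference"] = lf.reference
        f.attrs["spacing"] = lf.spacing
        f.attrs["truncation_order"] = lf.truncation_order
        f.attrs["head_label"] = lf.head_label
        if head is not None:
            f.attrs["head_radii"] = np.asarray(head.radii)
            f.attrs["head_conductivities"] = np.asarray(head.conductivities)


def import_leadfield(path, montage: Montage, space: SourceSpace) -> Leadfield:
    """Load and validate an externally computed leadfield; re-reference."""
    with h5py.File(path, "r") as f:
        gain = np.asarray(f["gain"])
        labels = [s.decode() for s in np.asarray(f["labels"])]
        spacing = float(f.attrs.get("spacing", space.spacing))
        order = int(f.attrs.get("truncation_order", 0))
        head_label = str(f.attrs.get("head_label", "imported"))
    n_eeg = len(montage.eeg_indices)
    if gain.shape[0] != n_eeg:
        raise ValueError(f"leadfield has {gain.shape[0]} channels, montage has {n_eeg}")
    if gain.shape[1] != space.n_sources:
        raise ValueError(f"leadfield has {gain.shape[1]} sources, "
                         f"space has {space.n_sources}")
    eeg_labels = [montage.labels[i] for i in montage.eeg_indices]
    if labels != eeg_labels:
        raise ValueError("leadfield channel labels do not match montage")
    # re-reference, but keep already-referenced gains bit-identical
    mean = gain.mean(axis=0, keepdims=True)
    if np.abs(mean).max() > 1e-9 * max(np.abs(gain).max(), 1e-300):
        gain = gain - mean
    return Leadfield(gain=gain, labels=labels, reference="average",
                     head_label=head_label, spacing=spacing,
                     truncation_order=order)


def standard_montage_positions(n: int, radius: float) -> np.ndarray:
    """Deterministic standard montage targets (quasi-uniform scalp coverage).

    Stands in for the 10-20-derived 32/64/128-channel layouts: the same
    golden-angle cap construction at the requested density.
    """
    return fib_points(n, radius)


def fib_points(n: int, radius: float) -> np.ndarray:
    from .geometry import fibonacci_cap_points
    return fibonacci_cap_points(n, radius, z_min_frac=0.0)


def subsample_montage(rec: Recording, montage: Montage,
                      target) -> tuple[Recording, Montage]:
    """Reduce to a standard lower-density montage by nearest-electrode pick.

    ``target`` is 32, 64, 128 or "full".  For each standard target position
    the nearest still-unused electrode is selected, assigning pairs globally
    by ascending match distance.  Pure channel selection: no resampling.
    """
    if target in ("full", rec.n_channels, None):
        return rec, montage
    n_target = int(target)
    if n_target not in (32, 64, 128):
        raise ValueError("target must be one of 32, 64, 128 or 'full'")
    eeg_idx = montage.eeg_indices
    if n_target > eeg_idx.size:
        raise ValueError("target montage larger than available EEG channels")
    eeg_pos = montage.positions[eeg_idx]
    radius = float(np.linalg.norm(eeg_pos, axis=1).mean())
    targets = standard_montage_positions(n_target, radius)

    dist = np.linalg.norm(targets[:, None, :] - eeg_pos[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    chosen = {}
    used = set()
    for ti, ei in order:
        if ti in chosen or ei in used:
            continue
        chosen[int(ti)] = int(ei)
        used.add(int(ei))
        if len(chosen) == n_target:
            break
    bad = [ti for ti, ei in chosen.items() if dist[ti, ei] > 0.03]
    if bad:
        raise ValueError(f"standard positions unmatchable within 0.03 m: {sorted(bad)}")
    sel_eeg = [eeg_idx[chosen[ti]] for ti in sorted(chosen)]
    sel = sel_eeg + list(montage.aux_indices)
    return rec.select_channels(sel), montage.subset(sel)
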