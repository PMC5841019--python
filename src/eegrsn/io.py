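"""File formats: the HDF5 array container, EDF export, and map writers."""

from __future__ import annotations

import numpy as np

from .containers import Montage, NetworkMap, Recording
from .forward import SourceSpace


def save_recording(path, rec: Recording, montage: Montage | None = None,
                   ground_truth_maps: list | None = None) -> None:
    """Package container: /data (uV), /fs, /labels, /kinds, /positions, ..."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        f.create_dataset("kinds", data=np.array(rec.kinds, dtype="S"))
        f.attrs["reference"] = rec.reference
        if montage is not None:
            f.create_dataset("positions", data=montage.positions)
        if ground_truth_maps:
            g = f.create_group("ground_truth_maps")
            for m in ground_truth_maps:
                g.create_dataset(m.name, data=m.values)


def load_recording(path):
    """Returns (Recording, Montage | None, list of ground-truth NetworkMaps)."""
    import h5py
    with h5py.File(path, "r") as f:
        labels = [s.decode() for s in np.asarray(f["labels"])]
        kinds = [s.decode() for s in np.asarray(f["kinds"])]
        rec = Recording(data=np.asarray(f["data"]), fs=float(np.asarray(f["fs"])),
                        labels=labels, kinds=kinds,
                        reference=str(f.attrs.get("reference", "raw")))
        montage = None
        if "positions" in f:
            montage = Montage(labels=labels, positions=np.asarray(f["positions"]),
                              kinds=kinds)
        maps = []
        if "ground_truth_maps" in f:
            for name in f["ground_truth_maps"]:
                maps.append(NetworkMap(values=np.asarray(f["ground_truth_maps"][name]),
                                       name=name))
    return rec, montage, maps


def _edf_pad(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: Recording) -> None:
    """Write a 16-bit EDF file (physical units uV), 1-s data records.

    Minimal standard-compliant writer: one signal per channel, per-channel
    physical scaling from the data range, trailing partial second dropped.
    """
    fs = rec.fs
    spr = int(round(fs))                 # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")
    n_sig = rec.n_channels
    data = rec.data[:, :n_rec * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _edf_pad("0", 8),
        _edf_pad("X X X X", 80),                 # patient id
        _edf_pad("Startdate X X X X", 80),       # recording id
        _edf_pad("01.01.00", 8), _edf_pad("00.00.00", 8),
        _edf_pad(256 * (1 + n_sig), 8),
        _edf_pad("", 44),
        _edf_pad(n_rec, 8),
        _edf_pad("1", 8),                        # record duration, s
        _edf_pad(n_sig, 4),
    ])
    fields = [
        (16, [f"{k} {l}" if k != "EEG" else f"EEG {l}"
              for l, k in zip(rec.labels, rec.kinds)]),
        (80, ["" for _ in range(n_sig)]),        # transducer
        (8, ["uV"] * n_sig),
        (8, [f"{v:.6g}"[:8] for v in pmin]),
        (8, [f"{v:.6g}"[:8] for v in pmax]),
        (8, [dmin] * n_sig),
        (8, [dmax] * n_sig),
        (80, ["" for _ in range(n_sig)]),        # prefiltering
        (8, [spr] * n_sig),
        (32, ["" for _ in range(n_sig)]),        # reserved
    ]
    sig_header = b"".join(b"".join(_edf_pad(v, w) for v in vals)
                          for w, vals in fields)
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())


def save_map_tsv(path, nm: NetworkMap, space: SourceSpace) -> None:
    """Flat per-source table: source_index, x, y, z, value."""
    with open(path, "w") as fh:
        fh.write("source_index\tx\ty\tz\tvalue\n")
        for i, (p, v) in enumerate(zip(space.positions, nm.values)):
            fh.write(f"{i}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{v:.8g}\n")


def save_map_nifti(path, nm: NetworkMap, space: SourceSpace) -> None:
    """Volumetric export of a source map on its lattice (NIfTI-1)."""
    import nibabel as nib
    if space.grid_ijk is None:
        raise ValueError("source space lacks lattice indices")
    vol = np.zeros(space.vol_shape, dtype=np.float32)
    vol[tuple(space.grid_ijk.T)] = nm.values
    affine = np.diag([space.spacing * 1000] * 3 + [1.0])  # mm voxels
    half = (np.array(space.vol_shape) - 1) / 2.0
    affine[:3, 3] = -half * space.spacing * 1000
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def save_operator(path, op, leadfield=None) -> None:
    """Operator container: /kernel, /method, /config (+ leadfield hash)."""
    import hashlib
    import json as _json

    import h5py

    from dataclasses import asdict
    with h5py.File(path, "w") as f:
        f.create_dataset("kernel", data=op.kernel)
        f.attrs["method"] = op.method
        f.attrs["config"] = _json.dumps(asdict(op.config))
        f.attrs["n_iterations"] = op.n_iterations
        if leadfield is not None:
            f.attrs["leadfield_sha1"] = hashlib.sha1(
                np.ascontiguousarray(leadfield.gain).tobytes()).hexdigest()


def load_operator(path, leadfield=None):
    """Load an operator container; verify leadfield provenance if given."""
    import hashlib
    import json as _json

    import h5py

    from .inverse import InverseConfig, InverseOperator
    with h5py.File(path, "r") as f:
        kernel = np.asarray(f["kernel"])
        method = str(f.attrs["method"])
        cfg = InverseConfig(**_json.loads(f.attrs["config"]))
        stored = f.attrs.get("leadfield_sha1")
        n_iter = int(f.attrs.get("n_iterations", 0))
    if leadfield is not None and stored is not None:
        got = hashlib.sha1(
            np.ascontiguousarray(leadfield.gain).tobytes()).hexdigest()
        if got != stored:
            raise ValueError("operator was built from a different leadfield")
    return InverseOperator(kernel=kernel, method=method, config=cfg,
                           n_iterations=n_iter)
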