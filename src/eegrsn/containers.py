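"""Core in-memory containers shared across the pipeline.

Conventions: head-centered coordinates in meters (+x right, +y anterior,
+z up); EEG data in microvolts (channels x samples); dipole moments in
nA*m with free orientation stored as 3 orthogonal components per source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

EEG = "EEG"
AUX_KINDS = ("hEOG", "vEOG", "EMG")


@dataclass
class Montage:
    """Electrode montage: labeled 3D sensor positions plus auxiliary channels."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), meters
    kinds: list[str]       # "EEG" or one of AUX_KINDS

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for k in self.kinds:
            if k != EEG and k not in AUX_KINDS:
                raise ValueError(f"unknown channel kind {k!r}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == EEG], dtype=int)

    @property
    def aux_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k != EEG], dtype=int)

    def aux_index(self, kind: str) -> int:
        """Index of the (single) auxiliary channel of the given kind."""
        idx = [i for i, k in enumerate(self.kinds) if k == kind]
        if len(idx) != 1:
            raise ValueError(f"montage has {len(idx)} channels of kind {kind!r}")
        return idx[0]

    @property
    def eeg_positions(self) -> np.ndarray:
        return self.positions[self.eeg_indices]

    def subset(self, indices: Sequence[int]) -> "Montage":
        indices = list(indices)
        return Montage(
            labels=[self.labels[i] for i in indices],
            positions=self.positions[indices].copy(),
            kinds=[self.kinds[i] for i in indices],
        )

    def save(self, path) -> None:
        """Write a whitespace-delimited ``label x y z`` text file (meters)."""
        with open(path, "w") as fh:
            for lab, pos in zip(self.labels, self.positions):
                fh.write(f"{lab} {pos[0]:.9f} {pos[1]:.9f} {pos[2]:.9f}\n")

    @classmethod
    def load(cls, path) -> "Montage":
        labels, positions = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                positions.append([float(v) for v in parts[1:4]])
        kinds = [lab if lab in AUX_KINDS else EEG for lab in labels]
        return cls(labels=labels, positions=np.asarray(positions), kinds=kinds)


@dataclass
class Recording:
    """Multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    labels: list[str]
    kinds: list[str]
    reference: str = "raw"  # "raw" | "average"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count must equal channel count")
        if len(self.kinds) != len(self.labels):
            raise ValueError("kind count must equal channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == EEG], dtype=int)

    @property
    def aux_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k != EEG], dtype=int)

    def aux_index(self, kind: str) -> int:
        idx = [i for i, k in enumerate(self.kinds) if k == kind]
        if len(idx) != 1:
            raise ValueError(f"recording has {len(idx)} channels of kind {kind!r}")
        return idx[0]

    @property
    def eeg_data(self) -> np.ndarray:
        return self.data[self.eeg_indices]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.labels),
                         list(self.kinds), self.reference)

    def crop(self, start: float, stop: float) -> "Recording":
        """Time-crop to [start, stop) seconds."""
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        return Recording(self.data[:, i0:i1].copy(), self.fs, list(self.labels),
                         list(self.kinds), self.reference)

    def select_channels(self, indices: Sequence[int]) -> "Recording":
        indices = list(indices)
        return Recording(self.data[indices].copy(), self.fs,
                         [self.labels[i] for i in indices],
                         [self.kinds[i] for i in indices], self.reference)


@dataclass
class SourceActivity:
    """Dipole moment time series on a source grid (nA*m).

    ``moments`` has shape (n_active, 3, n_samples).  When ``source_indices``
    is None the activity covers the whole grid; otherwise it covers only the
    listed source indices (all other sources are implicitly zero), which keeps
    long simulations with few active sources memory-bounded.
    """

    moments: np.ndarray
    fs: float
    n_sources: int
    source_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.moments = np.asarray(self.moments, dtype=float)
        if self.moments.ndim != 3 or self.moments.shape[1] != 3:
            raise ValueError("moments must be (n_active, 3, n_samples)")
        if self.source_indices is not None:
            self.source_indices = np.asarray(self.source_indices, dtype=int)
            if self.source_indices.shape[0] != self.moments.shape[0]:
                raise ValueError("source_indices length must match moments")
            if self.source_indices.size and self.source_indices.max() >= self.n_sources:
                raise ValueError("source index out of range")
        elif self.moments.shape[0] != self.n_sources:
            raise ValueError("full-grid moments must have n_sources rows")

    @property
    def n_samples(self) -> int:
        return self.moments.shape[2]

    def scaled(self, factor: float) -> "SourceActivity":
        return replace(self, moments=self.moments * factor)


@dataclass
class NetworkMap:
    """Per-source scalar map on a source space (IC map, template or statistic)."""

    values: np.ndarray
    name: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
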