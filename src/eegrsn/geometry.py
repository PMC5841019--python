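"""Deterministic point placement on the scalp sphere."""

from __future__ import annotations

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_cap_points(n: int, radius: float, z_min_frac: float = 0.0,
                         azimuth_offset: float = 0.0) -> np.ndarray:
    """Quasi-uniform points on the upper cap of a sphere.

    Places ``n`` points on the spherical cap ``z >= z_min_frac * radius``
    using the Fibonacci (golden-angle) spiral, which gives near-optimal
    packing for any n.  Deterministic; ``azimuth_offset`` rotates the whole
    spiral about z.

    Returns an (n, 3) array in meters.
    """
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n)
    # uniform area sampling of z over the cap, offset half a step from edges
    z = z_min_frac + (1.0 - z_min_frac) * (k + 0.5) / n
    phi = GOLDEN_ANGLE * k + azimuth_offset
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return radius * pts


def pairwise_min_great_circle(points: np.ndarray) -> float:
    """Smallest pairwise great-circle distance among points on a sphere."""
    radius = float(np.linalg.norm(points, axis=1).mean())
    unit = points / np.linalg.norm(points, axis=1, keepdims=True)
    dots = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)
    return radius * float(np.arccos(dots.max()))
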