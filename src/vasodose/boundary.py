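"""Organ boundaries for tree growth: analytic shapes or binary voxel masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Boundary:
    """Interface: point containment plus seeded interior sampling."""

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover - interface
        raise NotImplementedError

    def sample_interior(self, n: int, rng: np.random.Generator, max_tries: int = 10_000) -> np.ndarray:
        """Rejection-sample ``n`` strictly interior points from the bounding box."""
        lo, hi = self.bounds()
        out = np.empty((n, 3))
        got = 0
        for _ in range(max_tries):
            m = max(2 * (n - got), 16)
            cand = lo + (hi - lo) * rng.random((m, 3))
            good = cand[self.contains(cand)]
            take = min(len(good), n - got)
            out[got : got + take] = good[:take]
            got += take
            if got == n:
                return out
        raise RuntimeError("boundary interior sampling failed: zero or vanishing interior volume")


@dataclass
class SphereBoundary(Boundary):
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 1.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - np.asarray(self.center, float)
        return (p * p).sum(axis=1) < self.radius**2

    def bounds(self):
        c = np.asarray(self.center, float)
        return c - self.radius, c + self.radius


@dataclass
class BoxBoundary(Boundary):
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        return ((p > lo) & (p < hi)).all(axis=1)

    def bounds(self):
        return np.asarray(self.lo, float), np.asarray(self.hi, float)


@dataclass
class VoxelMaskBoundary(Boundary):
    """Binary occupancy mask with isotropic spacing (mm); origin at voxel (0,0,0) corner."""

    mask: np.ndarray
    spacing: float = 0.3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask has zero interior volume")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = (np.atleast_2d(points) - np.asarray(self.origin, float)) / self.spacing
        idx = np.floor(p).astype(int)
        ok = ((idx >= 0) & (idx < self.mask.shape)).all(axis=1)
        out = np.zeros(len(p), bool)
        ii = idx[ok]
        out[ok] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def bounds(self):
        o = np.asarray(self.origin, float)
        return o, o + self.spacing * np.array(self.mask.shape)
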