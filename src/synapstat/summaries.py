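"""Second-order summary statistics in 3D.

The workhorse is the translation-corrected (Miles-Lantuejoul-Stoyan-Hanisch)
estimator of Ripley's K function for a pattern of N points in a box B:

    K(d) = vol(B)^2 / N^2 * sum_{k != l} 1{ |x_k - x_l| <= d } / gamma_B(x_k - x_l)

where gamma_B(v) is the set covariance of the box, the volume of B
intersected with B shifted by v; for an axis-aligned box it is the product
of the clipped side lengths. The N^2 normalization (not N(N-1)) is used
deliberately. Besag's L function is the variance-stabilizing cube-root
transform, L(d) = (3 K(d) / 4 pi)^(1/3), mapping complete spatial
randomness (CSR) onto the diagonal L(d) = d.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from synapstat.patterns import Box3D, PointPattern3D

#: default fraction of the shortest box side used as the maximum distance:
#: the translation correction degrades (gamma_B -> 0) as d approaches the
#: box dimensions, so the grid stays well inside the window.
DEFAULT_RMAX_FRACTION = 0.25
DEFAULT_GRID_SIZE = 128


@dataclass(frozen=True)
class DistanceGrid:
    """Strictly increasing distances (nm) starting at 0."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        v = self.values
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two distances")
        if v[0] != 0.0 or np.any(np.diff(v) <= 0):
            raise ValueError("grid must start at 0 and be strictly increasing")

    @property
    def r_max(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def default_for_box(
        cls,
        box: Box3D,
        n: int = DEFAULT_GRID_SIZE,
        max_fraction: float = DEFAULT_RMAX_FRACTION,
    ) -> "DistanceGrid":
        return cls(np.linspace(0.0, max_fraction * box.min_side, n))

    @classmethod
    def default_for_boxes(cls, boxes, n: int = DEFAULT_GRID_SIZE) -> "DistanceGrid":
        """A grid valid for every box: r_max from the smallest min-side."""
        min_side = min(b.min_side for b in boxes)
        return cls(np.linspace(0.0, DEFAULT_RMAX_FRACTION * min_side, n))


@dataclass
class SummaryFunction:
    """K (nm^3) or L (nm) values on a distance grid."""

    grid: DistanceGrid
    values: np.ndarray
    kind: str  # "K" or "L"
    n_points: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("K", "L"):
            raise ValueError("kind must be 'K' or 'L'")
        if self.values.shape != self.grid.values.shape:
            raise ValueError("values must match the grid length")


def set_covariance(box: Box3D, v: np.ndarray) -> float:
    """Set covariance gamma_B(v) of an axis-aligned box: volume of overlap
    between the box and its translate by v."""
    v = np.asarray(v, dtype=float)
    return float(np.prod(np.clip(box.side_lengths - np.abs(v), 0.0, None)))


def k3_translation(
    pattern: PointPattern3D, grid: DistanceGrid | None = None
) -> SummaryFunction:
    """Translation-corrected estimate of Ripley's K on a distance grid.

    Pairs with zero set covariance cannot occur for d below the shortest box
    side; they are excluded defensively with a warning if they ever appear.
    """
    if pattern.n_points < 2:
        raise ValueError("K estimation needs at least 2 points")
    box = pattern.box
    if grid is None:
        grid = DistanceGrid.default_for_box(box)
    if grid.r_max > box.min_side:
        raise ValueError("grid exceeds the box: translation correction undefined")

    x = pattern.coords
    n = pattern.n_points
    diff = x[:, None, :] - x[None, :, :]
    gamma = np.prod(box.side_lengths - np.abs(diff), axis=2)
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    iu = ~np.eye(n, dtype=bool)
    dist = dist[iu]
    gamma = gamma[iu]
    in_range = dist <= grid.r_max
    dist = dist[in_range]
    gamma = gamma[in_range]
    bad = gamma <= 0
    if np.any(bad):
        warnings.warn("excluded pairs with zero set covariance", stacklevel=2)
        dist, gamma = dist[~bad], gamma[~bad]

    order = np.argsort(dist)
    dist = dist[order]
    csum = np.concatenate([[0.0], np.cumsum(1.0 / gamma[order])])
    idx = np.searchsorted(dist, grid.values, side="right")
    k = (box.volume_nm3**2 / n**2) * csum[idx]
    return SummaryFunction(grid=grid, values=k, kind="K", n_points=n)


def k_csr(grid: DistanceGrid) -> SummaryFunction:
    """Closed-form K under complete spatial randomness: (4/3) pi d^3."""
    return SummaryFunction(
        grid=grid, values=(4.0 / 3.0) * np.pi * grid.values**3, kind="K"
    )


def l_from_k(k: SummaryFunction) -> SummaryFunction:
    """Besag's L transform, elementwise (3K / 4 pi)^(1/3)."""
    if np.any(k.values < 0):
        raise ValueError("K values must be non-negative")
    values = np.cbrt(3.0 * k.values / (4.0 * np.pi))
    return SummaryFunction(grid=k.grid, values=values, kind="L", n_points=k.n_points)


def write_summary(summary: SummaryFunction, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    pd.DataFrame({"d_nm": summary.grid.values, "value": summary.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
    path.with_suffix(".json").write_text(
        json.dumps({"kind": summary.kind, "n_points": summary.n_points})
    )
    return path
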