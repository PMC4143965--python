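"""Point-process simulators: CSR, RSA hard spheres, and random thinning.

The random sequential adsorption (RSA) simulator models synapses as
non-overlapping spheres: spheres with lognormally distributed Feret
diameters are dropped uniformly at random one at a time; a candidate that
intersects any accepted sphere is discarded and a fresh location *and* a
fresh diameter are drawn; placement continues until the target intensity
(count) is reached. Under the default ``half_feret`` convention the sphere
circumscribing a synapse has radius Feret/2, so two centroids may not lie
closer than (D_k + D_l)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from synapstat.patterns import Box3D, PointPattern3D
from synapstat.util import as_rng


@dataclass(frozen=True)
class LognormalSize:
    """Lognormal law for Feret diameters; ``mu``/``sigma`` on the log-nm scale."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    @property
    def mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class RSAParams:
    """RSA model parameters: intensity (per um^3) plus the size law."""

    intensity: float
    size: LognormalSize
    radius_convention: str = "half_feret"

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.radius_convention not in ("half_feret", "full_feret"):
            raise ValueError("radius_convention must be half_feret or full_feret")

    def exclusion_radius(self, feret: np.ndarray) -> np.ndarray:
        """Per-sphere exclusion radius implied by a Feret diameter."""
        feret = np.asarray(feret, dtype=float)
        return feret / 2.0 if self.radius_convention == "half_feret" else feret


class RSAJammingError(RuntimeError):
    """Raised when the rejection budget is exhausted before the target count."""

    def __init__(self, target: int, achieved: int, max_consecutive_rejections: int):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"RSA jammed: placed {achieved}/{target} spheres before "
            f"{max_consecutive_rejections} consecutive rejections"
        )


def target_count(intensity: float, box: Box3D) -> int:
    return int(np.rint(intensity * box.volume_um3))


def simulate_csr(
    box: Box3D,
    intensity: float,
    seed=None,
    fixed_n: bool = False,
    **metadata,
) -> PointPattern3D:
    """Homogeneous Poisson (CSR) pattern; ``fixed_n`` pins the count to
    round(intensity * volume) instead of drawing it Poisson."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = as_rng(seed)
    n = target_count(intensity, box) if fixed_n else rng.poisson(
        intensity * box.volume_um3
    )
    coords = box.origin + rng.random((n, 3)) * box.side_lengths
    return PointPattern3D(box=box, coords=coords, feret=None, **metadata)


def simulate_rsa(
    box: Box3D,
    params: RSAParams,
    seed=None,
    max_consecutive_rejections: int = 10_000,
    **metadata,
) -> PointPattern3D:
    """RSA hard-sphere pattern with exactly round(intensity * volume) points.

    At the study's densities (~1.4 per um^3 with ~400 nm spheres, packing
    fraction around 5%) jamming is far away; the rejection budget is a
    safety net that reports the achieved count if ever hit.
    """
    rng = as_rng(seed)
    target = target_count(params.intensity, box)
    coords = np.empty((target, 3))
    ferets = np.empty(target)
    radii = np.empty(target)
    n = 0
    consecutive = 0
    chunk = 128
    while n < target:
        pos = box.origin + rng.random((chunk, 3)) * box.side_lengths
        diam = params.size.sample(rng, chunk)
        rad = params.exclusion_radius(diam)
        for i in range(chunk):
            if n == target:
                break
            if n:
                delta = coords[:n] - pos[i]
                sq = np.einsum("ij,ij->i", delta, delta)
                if np.any(sq < (radii[:n] + rad[i]) ** 2):
                    consecutive += 1
                    if consecutive >= max_consecutive_rejections:
                        raise RSAJammingError(target, n, max_consecutive_rejections)
                    continue
            coords[n] = pos[i]
            ferets[n] = diam[i]
            radii[n] = rad[i]
            n += 1
            consecutive = 0
    return PointPattern3D(box=box, coords=coords, feret=ferets, **metadata)


def thin_to_intensity(
    pattern: PointPattern3D, target_intensity: float, seed=None
) -> PointPattern3D:
    """Uniformly random subset with round(target * volume) points.

    Retained points keep their coordinates and diameters, so a hard-core
    pattern stays hard-core (a subset of a non-overlapping set).
    """
    if target_intensity < 0:
        raise ValueError("target intensity must be non-negative")
    m = target_count(target_intensity, pattern.box)
    if m > pattern.n_points:
        raise ValueError(
            f"target intensity {target_intensity} exceeds current "
            f"intensity {pattern.intensity:.4g}"
        )
    rng = as_rng(seed)
    keep = np.sort(rng.choice(pattern.n_points, size=m, replace=False))
    feret = None if pattern.feret is None else pattern.feret[keep]
    return PointPattern3D(
        box=pattern.box,
        coords=pattern.coords[keep],
        feret=feret,
        layer=pattern.layer,
        animal=pattern.animal,
        sample_id=pattern.sample_id,
    )


def fit_lognormal(diameters) -> LognormalSize:
    """Maximum-likelihood lognormal fit: mean and population SD of the logs."""
    d = np.asarray(diameters, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("need at least 2 diameters to fit a lognormal")
    if np.any(d <= 0):
        raise ValueError("diameters must be strictly positive")
    logs = np.log(d)
    sigma = float(np.std(logs))  # population SD (MLE)
    if sigma == 0:
        raise ValueError("degenerate fit: all diameters identical")
    return LognormalSize(mu=float(np.mean(logs)), sigma=sigma)
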