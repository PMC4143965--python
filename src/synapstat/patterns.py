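"""Core data model for 3D synapse point patterns: boxes, patterns, studies, I/O.

Coordinates and Feret diameters are stored in nanometres; intensities are
reported in synapses per cubic micron. Box membership is half-open per axis,
``origin <= coord < origin + side``, so tiling a window never double-counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from synapstat.util import NM3_PER_UM3


class SynapsePoint(NamedTuple):
    """A single synapse: centroid (nm) and optional Feret diameter (nm)."""

    x: float
    y: float
    z: float
    feret_diameter: float | None = None


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned rectangular observation window, sides in nm."""

    side_lengths: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(
            self, "side_lengths", np.asarray(self.side_lengths, dtype=float)
        )
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.side_lengths.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("side_lengths and origin must be 3-vectors")
        if not np.all(self.side_lengths > 0):
            raise ValueError("all box side lengths must be positive")

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.side_lengths))

    @property
    def volume_um3(self) -> float:
        return self.volume_nm3 / NM3_PER_UM3

    @property
    def min_side(self) -> float:
        return float(np.min(self.side_lengths))

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Half-open membership test for an (n, 3) array of coordinates."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = coords >= self.origin
        hi = coords < self.origin + self.side_lengths
        return np.all(lo & hi, axis=1)


@dataclass
class PointPattern3D:
    """A point pattern: synapse centroids (and sizes) inside a box window.

    Parameters
    ----------
    box : Box3D
        Observation window.
    coords : (n, 3) array
        Centroid coordinates in nm.
    feret : (n,) array or None
        Feret diameters in nm; NaN marks a missing diameter. ``None`` means
        no diameters at all.
    layer, animal, sample_id : str
        Study metadata. ``layer`` is a cortical layer label I..VI when given.
    """

    box: Box3D
    coords: np.ndarray
    feret: np.ndarray | None = None
    layer: str | None = None
    animal: str | None = None
    sample_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.feret is not None:
            self.feret = np.asarray(self.feret, dtype=float).reshape(-1)
            if self.feret.shape[0] != self.coords.shape[0]:
                raise ValueError("feret length must match number of points")
            present = ~np.isnan(self.feret)
            if np.any(self.feret[present] <= 0):
                raise ValueError("Feret diameters must be positive when present")
            if not np.any(present):
                self.feret = None
        if self.coords.shape[0] and not np.all(self.box.contains(self.coords)):
            raise ValueError("every point must lie inside the box window")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def intensity(self) -> float:
        """Estimated intensity, synapses per um^3."""
        return self.n_points / self.box.volume_um3

    @property
    def points(self) -> list[SynapsePoint]:
        out = []
        for i in range(self.n_points):
            d = None
            if self.feret is not None and not np.isnan(self.feret[i]):
                d = float(self.feret[i])
            out.append(SynapsePoint(*map(float, self.coords[i]), d))
        return out

    def with_metadata(self, **kwargs) -> "PointPattern3D":
        return replace(self, **kwargs)


@dataclass
class StudyCollection:
    """Replicated patterns grouped by cortical layer and by animal."""

    patterns: list[PointPattern3D]

    def __post_init__(self):
        keys = [(p.layer, p.sample_id) for p in self.patterns]
        if len(set(keys)) != len(keys):
            raise ValueError("(layer, sample_id) pairs must be unique")

    def __iter__(self) -> Iterator[PointPattern3D]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def layers(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.patterns:
            if p.layer is not None:
                seen.setdefault(p.layer, None)
        return list(seen)

    def by_layer(self, layer: str) -> list[PointPattern3D]:
        out = [p for p in self.patterns if p.layer == layer]
        if not out:
            raise KeyError(f"no samples in layer {layer!r}")
        return out

    def by_animal(self, animal: str) -> list[PointPattern3D]:
        out = [p for p in self.patterns if p.animal == animal]
        if not out:
            raise KeyError(f"no samples for animal {animal!r}")
        return out

    @property
    def animals(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.patterns:
            if p.animal is not None:
                seen.setdefault(p.animal, None)
        return list(seen)

    def get(self, layer: str, sample_id: str) -> PointPattern3D:
        for p in self.patterns:
            if p.layer == layer and p.sample_id == sample_id:
                return p
        raise KeyError(f"sample ({layer!r}, {sample_id!r}) not found")


# ---------------------------------------------------------------------------
# descriptive statistics


def estimate_intensity(pattern: PointPattern3D) -> float:
    """Point count divided by window volume, in synapses per um^3."""
    vol = pattern.box.volume_um3
    if vol <= 0:
        raise ValueError("box volume must be positive")
    return pattern.n_points / vol


def shrinkage_correct(
    pattern: PointPattern3D, linear_factor: float = 0.90
) -> PointPattern3D:
    """Undo tissue shrinkage by dividing all linear measures by the factor.

    Osmication and embedding shrink tissue; with a linear factor of 0.90 the
    volume factor is 0.90^3 ~= 0.73. Coordinates, diameters, box sides and
    the box origin are all divided by ``linear_factor``, so volumes come out
    divided by the cube of it.
    """
    if not 0 < linear_factor <= 1:
        raise ValueError("linear shrinkage factor must be in (0, 1]")
    box = Box3D(
        side_lengths=pattern.box.side_lengths / linear_factor,
        origin=pattern.box.origin / linear_factor,
    )
    feret = None if pattern.feret is None else pattern.feret / linear_factor
    return PointPattern3D(
        box=box,
        coords=pattern.coords / linear_factor,
        feret=feret,
        layer=pattern.layer,
        animal=pattern.animal,
        sample_id=pattern.sample_id,
    )


def nearest_neighbor_distances(pattern: PointPattern3D) -> np.ndarray:
    """Euclidean distance from each centroid to its nearest neighbour, nm.

    Raw distances, no edge correction: this mirrors the descriptive use of
    nearest-neighbour distances in sample summary tables.
    """
    if pattern.n_points < 2:
        raise ValueError("need at least 2 points for nearest-neighbour distances")
    tree = cKDTree(pattern.coords)
    dist, _ = tree.query(pattern.coords, k=2)
    return dist[:, 1]


# ---------------------------------------------------------------------------
# I/O: CSV of points + JSON sidecar, and YAML study manifests

_CSV_COLUMNS = ["x_nm", "y_nm", "z_nm", "feret_nm"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_pattern(pattern: PointPattern3D, path: str | Path) -> Path:
    """Write a pattern as ``<path>.csv`` plus a JSON sidecar with the window."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    feret = (
        pattern.feret
        if pattern.feret is not None
        else np.full(pattern.n_points, np.nan)
    )
    df = pd.DataFrame(
        {
            "x_nm": pattern.coords[:, 0],
            "y_nm": pattern.coords[:, 1],
            "z_nm": pattern.coords[:, 2],
            "feret_nm": feret,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "box_side_nm": pattern.box.side_lengths.tolist(),
        "box_origin_nm": pattern.box.origin.tolist(),
        "layer": pattern.layer,
        "animal": pattern.animal,
        "sample_id": pattern.sample_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_pattern(path: str | Path) -> PointPattern3D:
    """Read a pattern from its CSV; the JSON sidecar must sit next to it."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    box = Box3D(
        side_lengths=np.asarray(meta["box_side_nm"], dtype=float),
        origin=np.asarray(meta.get("box_origin_nm", [0.0, 0.0, 0.0]), dtype=float),
    )
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pattern CSV lacks columns {missing}")
    coords = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    feret = df["feret_nm"].to_numpy(dtype=float)
    if np.all(np.isnan(feret)):
        feret = None
    return PointPattern3D(
        box=box,
        coords=coords,
        feret=feret,
        layer=meta.get("layer"),
        animal=meta.get("animal"),
        sample_id=meta.get("sample_id", path.stem),
    )


def write_study(study: StudyCollection, directory: str | Path) -> Path:
    """Write every sample plus a ``manifest.yaml`` listing them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in study:
        stem = f"{p.layer or 'X'}_{p.sample_id}".replace("/", "-")
        csv_path = write_pattern(p, directory / f"{stem}.csv")
        entries.append(
            {
                "file": csv_path.name,
                "layer": p.layer,
                "animal": p.animal,
                "sample_id": p.sample_id,
            }
        )
    manifest = directory / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"samples": entries}, sort_keys=False))
    return manifest


def read_study(manifest_path: str | Path) -> StudyCollection:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"study manifest {manifest_path} not found")
    manifest = yaml.safe_load(manifest_path.read_text())
    patterns = []
    for entry in manifest["samples"]:
        p = read_pattern(manifest_path.parent / entry["file"])
        patterns.append(
            p.with_metadata(
                layer=entry.get("layer", p.layer),
                animal=entry.get("animal", p.animal),
                sample_id=entry.get("sample_id", p.sample_id),
            )
        )
    return StudyCollection(patterns)


def pooled_intensity(patterns: Sequence[PointPattern3D]) -> float:
    """Total count over total volume for a set of samples, per um^3."""
    counts = sum(p.n_points for p in patterns)
    vols = sum(p.box.volume_um3 for p in patterns)
    return counts / vols
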