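"""Synthetic study generator emulating the experimental design.

Each synthetic sample is an independent RSA hard-sphere simulation inside
a box with the acquisition field of view (7.6 x 5.7 um) and a depth equal
to a whole number of 20 nm sections chosen so box volumes match the
published per-layer mean volumes. Per-layer intensities are the published
layer means; Feret diameters share the global lognormal law. A
``core_scale`` > 1 inflates the exclusion diameters of a layer (leaving
intensity fixed) to emulate a layer with stronger repulsion between
synapses, with the inflated diameters carried on the points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from synapstat.patterns import Box3D, PointPattern3D, StudyCollection
from synapstat.reference import (
    FOV_X_NM,
    FOV_Y_NM,
    LAYER_MEANS,
    MU_GLOBAL,
    SECTION_THICKNESS_NM,
    SIGMA_GLOBAL,
)
from synapstat.simulate import LognormalSize, RSAParams, simulate_rsa
from synapstat.util import NM3_PER_UM3, as_rng

#: replicates per layer in the emulated study design
_LAYER_SAMPLE_COUNTS = {"I": 2, "II": 3, "III": 10, "IV": 3, "V": 3, "VI": 4}

#: animals assigned round-robin, as in a multi-animal design
_ANIMALS = ("w31", "w33", "w35")


@dataclass(frozen=True)
class LayerSpec:
    """Generation recipe for one layer's replicates."""

    label: str
    intensity: float  # synapses per um^3
    size: LognormalSize
    n_samples: int
    box_sides_nm: np.ndarray
    core_scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "box_sides_nm", np.asarray(self.box_sides_nm, dtype=float)
        )
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.core_scale < 1:
            raise ValueError("core_scale must be >= 1")


def _layer_box_sides(mean_volume_um3: float) -> np.ndarray:
    """Box with the acquisition FOV and a whole number of 20 nm sections
    whose volume is closest to the published layer mean volume."""
    section_vol = FOV_X_NM * FOV_Y_NM * SECTION_THICKNESS_NM
    n_sections = int(np.rint(mean_volume_um3 * NM3_PER_UM3 / section_vol))
    return np.array([FOV_X_NM, FOV_Y_NM, n_sections * SECTION_THICKNESS_NM])


def default_study_spec(core_scale_by_layer: dict | None = None) -> list[LayerSpec]:
    """Six LayerSpecs matching the published study design.

    Intensities and mean volumes are the published per-layer values; all
    layers share the global lognormal size law. ``core_scale_by_layer``
    optionally inflates the exclusion diameters of chosen layers to build
    contrast ("layer I-like") configurations.
    """
    core_scale_by_layer = core_scale_by_layer or {}
    size = LognormalSize(mu=MU_GLOBAL, sigma=SIGMA_GLOBAL)
    specs = []
    for label, (mean_vol, _count, density) in LAYER_MEANS.items():
        specs.append(
            LayerSpec(
                label=label,
                intensity=density,
                size=size,
                n_samples=_LAYER_SAMPLE_COUNTS[label],
                box_sides_nm=_layer_box_sides(mean_vol),
                core_scale=core_scale_by_layer.get(label, 1.0),
            )
        )
    return specs


def generate_study(spec: list[LayerSpec] | None = None, seed=None) -> StudyCollection:
    """Generate a synthetic study: one RSA simulation per sample.

    A ``core_scale`` > 1 shifts the log-mean of the simulated diameters by
    log(core_scale), i.e. every exclusion diameter is multiplied by the
    scale; the inflated diameters are stored on the points.
    """
    if spec is None:
        spec = default_study_spec()
    rng = as_rng(seed)
    patterns = []
    animal_cursor = 0
    for layer in spec:
        size = layer.size
        if layer.core_scale != 1.0:
            size = LognormalSize(
                mu=layer.size.mu + float(np.log(layer.core_scale)),
                sigma=layer.size.sigma,
            )
        params = RSAParams(intensity=layer.intensity, size=size)
        box = Box3D(side_lengths=layer.box_sides_nm)
        for k in range(layer.n_samples):
            p = simulate_rsa(
                box,
                params,
                seed=rng,
                layer=layer.label,
                animal=_ANIMALS[animal_cursor % len(_ANIMALS)],
                sample_id=str(k + 1),
            )
            patterns.append(p)
            animal_cursor += 1
    return StudyCollection(patterns)
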