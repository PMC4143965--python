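"""Dense global RSA model, random thinning, and envelope cross-validation.

The hypothesis under test: a set of layers shares one underlying RSA
process and differs only in intensity (each layer is a thinned version of
the common process). The procedure:

1. Fit a *dense* global model: lambda_global is 1% above the maximum
   per-sample intensity of the member layers (rounded to one decimal by
   default), and the size law is the lognormal fit of the pooled Feret
   diameters of all member samples. Simulate n_dense (default 198) RSA
   patterns at lambda_global once; they are reused for every held-out
   sample.
2. For each held-out sample j of layer i, estimate lambda_ij from the
   other samples of its layer (leave-one-out, volume-weighted) and thin
   every dense simulation down to lambda_ij. Thinning deletes points
   uniformly at random, so the hard-core structure is inherited.
3. Test the held-out sample against the thinned simulations with a global
   envelope: the first half of the thinned patterns gives the central L
   curve, the second half gives w_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from synapstat.envelopes import EnvelopeResult, envelope_verdict, loo_intensity
from synapstat.patterns import Box3D, PointPattern3D, StudyCollection
from synapstat.reference import FOV_X_NM, FOV_Y_NM
from synapstat.simulate import RSAParams, fit_lognormal, simulate_rsa, thin_to_intensity
from synapstat.summaries import DistanceGrid, k3_translation, l_from_k
from synapstat.util import NM3_PER_UM3, as_rng

#: default dense-simulation window volume, um^3
DEFAULT_DENSE_VOLUME_UM3 = 300.0


def default_dense_box(volume_um3: float = DEFAULT_DENSE_VOLUME_UM3) -> Box3D:
    """A box with the acquisition field of view and the depth that gives
    the requested volume."""
    depth = volume_um3 * NM3_PER_UM3 / (FOV_X_NM * FOV_Y_NM)
    return Box3D(side_lengths=np.array([FOV_X_NM, FOV_Y_NM, depth]))


@dataclass
class GlobalModel:
    """A fitted dense global RSA model and its reusable dense simulations."""

    params: RSAParams
    member_layers: list
    dense: list  # list of PointPattern3D at lambda_global
    box: Box3D
    seed: object = None

    @property
    def n_dense(self) -> int:
        return len(self.dense)


def global_intensity(
    max_sample_intensity: float, headroom: float = 1.01, round_decimals: int | None = 1
) -> float:
    """lambda_global: 1% above the densest sample, rounded up to one decimal.

    Rounding up (ceiling) rather than to-nearest keeps the defining
    invariant lambda_global > lambda_ij for every sample: rounding to
    nearest can land below the densest sample's leave-one-out intensity.
    """
    lam = headroom * max_sample_intensity
    if round_decimals is None:
        return lam
    scale = 10.0**round_decimals
    return float(np.ceil(lam * scale) / scale)


def fit_global_model(
    study: StudyCollection,
    layers: list | None = None,
    volume_box: Box3D | None = None,
    n_dense: int = 198,
    seed=None,
    round_decimals: int | None = 1,
    radius_convention: str = "half_feret",
) -> GlobalModel:
    """Fit lambda_global and the pooled size law, then run the dense simulations."""
    if layers is None:
        layers = study.layers
    if not layers:
        raise ValueError("no member layers")
    members = [p for lab in layers for p in study.by_layer(lab)]
    lam = global_intensity(
        max(p.intensity for p in members), round_decimals=round_decimals
    )
    pools = [p.feret[~np.isnan(p.feret)] for p in members if p.feret is not None]
    if not pools:
        raise ValueError("member samples carry no Feret diameters")
    size = fit_lognormal(np.concatenate(pools))
    params = RSAParams(intensity=lam, size=size, radius_convention=radius_convention)
    if volume_box is None:
        volume_box = default_dense_box()
    rng = as_rng(seed)
    dense = [simulate_rsa(volume_box, params, seed=rng) for _ in range(n_dense)]
    return GlobalModel(
        params=params, member_layers=list(layers), dense=dense, box=volume_box,
        seed=seed,
    )


def thinning_cv_run(
    study: StudyCollection,
    model: GlobalModel,
    layer: str,
    sample_id: str,
    seed=None,
    grid: DistanceGrid | None = None,
) -> EnvelopeResult:
    """Envelope verdict for one held-out sample against the thinned model."""
    sample = study.get(layer, sample_id)
    lam = loo_intensity(study, layer, sample_id)
    if lam > model.params.intensity:
        raise ValueError(
            f"leave-one-out intensity {lam:.4g} exceeds lambda_global "
            f"{model.params.intensity:.4g}"
        )
    rng = as_rng(seed)
    if grid is None:
        grid = DistanceGrid.default_for_boxes([sample.box, model.box])
    observed = l_from_k(k3_translation(sample, grid)).values
    sims = np.empty((model.n_dense, len(grid)))
    for s, dense in enumerate(model.dense):
        thinned = thin_to_intensity(dense, lam, seed=rng)
        sims[s] = l_from_k(k3_translation(thinned, grid)).values
    half = model.n_dense // 2
    return envelope_verdict(observed, sims[:half], sims[half:], grid)


def thinning_cv_sweep(
    study: StudyCollection,
    model: GlobalModel,
    seed=None,
    grid: DistanceGrid | None = None,
) -> pd.DataFrame:
    """Cross-validate every member sample; one verdict row per sample."""
    members = [p for lab in model.member_layers for p in study.by_layer(lab)]
    if not members:
        raise ValueError("global model has no member samples")
    if grid is None:
        boxes = [p.box for p in members] + [model.box]
        grid = DistanceGrid.default_for_boxes(boxes)
    rng = as_rng(seed)
    rows = []
    for p in members:
        res = thinning_cv_run(study, model, p.layer, p.sample_id, seed=rng, grid=grid)
        rows.append(
            {
                "layer": p.layer,
                "sample_id": p.sample_id,
                "lambda_loo": loo_intensity(study, p.layer, p.sample_id),
                "reject": res.reject,
                "exceed_distances": list(res.exceed_distances),
            }
        )
    return pd.DataFrame(rows)
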