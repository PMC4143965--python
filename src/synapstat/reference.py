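"""Published per-sample summary statistics of the rat somatosensory cortex study.

The original centroid clouds are not public, but the per-sample windows,
synapse counts and densities were published, as were the leave-one-out
intensity estimates and the global lognormal Feret-diameter fit. Those
printed numbers are sufficient inputs for the density bookkeeping, the
leave-one-out arithmetic and the global thinning model, and they
parameterize the synthetic study generator.

All volumes are um^3, densities synapses/um^3, diameters nm.
"""

from __future__ import annotations

import pandas as pd

#: FIB/SEM acquisition geometry: field of view and section thickness.
FOV_X_NM = 7600.0
FOV_Y_NM = 5700.0
SECTION_THICKNESS_NM = 20.0

#: global lognormal fit of Feret diameters (log-nm scale), layers II-VI pooled
MU_GLOBAL = 5.911
SIGMA_GLOBAL = 0.404

#: observed overall mean Feret diameter, nm
MEAN_FERET_NM = 404.73

#: linear tissue shrinkage factor (area 0.81, volume 0.73 follow from it)
LINEAR_SHRINKAGE = 0.90

# (layer, sample, animal, volume_um3, n_synapses, printed density per um3)
_SAMPLE_ROWS = [
    ("I", "1", "w33", 210.61, 180, 0.855),
    ("I", "2", "w35", 177.20, 128, 0.722),
    ("II", "1", "w33", 224.35, 230, 1.025),
    ("II", "2", "w35", 139.51, 127, 0.910),
    ("II", "3", "w35", 149.03, 206, 1.382),
    ("III", "1", "w31", 149.13, 147, 0.986),
    ("III", "2", "w31", 157.15, 109, 0.694),
    ("III", "3", "w33", 186.45, 173, 0.928),
    ("III", "4", "w33", 176.44, 178, 1.009),
    ("III", "5", "w33", 176.28, 167, 0.947),
    ("III", "6", "w33", 175.55, 165, 0.940),
    ("III", "7", "w33", 191.28, 189, 0.988),
    ("III", "8", "w35", 247.58, 198, 0.800),
    ("III", "9", "w35", 178.40, 201, 1.127),
    ("III", "10", "w35", 165.06, 168, 1.018),
    ("IV", "1", "w33", 154.59, 172, 1.113),
    ("IV", "2", "w35", 140.63, 178, 1.266),
    ("IV", "3", "w35", 123.81, 162, 1.308),
    ("V", "1", "w33", 165.62, 117, 0.706),
    ("V", "2", "w33", 218.01, 198, 0.908),
    ("V", "3", "w33", 207.95, 175, 0.842),
    ("VI", "1", "w33", 185.32, 92, 0.496),
    ("VI", "2", "w35", 183.55, 85, 0.463),
    ("VI", "3", "w31", 179.97, 102, 0.567),
    ("VI", "4", "w31", 280.09, 107, 0.382),
]


def sample_table() -> pd.DataFrame:
    """Per-sample window volume, synapse count and printed density."""
    return pd.DataFrame(
        _SAMPLE_ROWS,
        columns=["layer", "sample", "animal", "volume_um3", "n_synapses", "density"],
    )


#: printed per-layer summary (mean volume, rounded mean count, pooled density)
LAYER_MEANS = {
    "I": (193.91, 154, 0.794),
    "II": (170.96, 188, 1.098),
    "III": (180.33, 170, 0.940),
    "IV": (139.68, 171, 1.222),
    "V": (197.19, 163, 0.828),
    "VI": (207.23, 97, 0.466),
}

#: printed study totals: total count and overall pooled density
TOTAL_SYNAPSES = 3954
OVERALL_DENSITY = 0.870

#: printed leave-one-out intensity estimates for layers II-VI, per um^3
LOO_INTENSITY = {
    ("II", "1"): 1.154,
    ("II", "2"): 1.168,
    ("II", "3"): 0.981,
    ("III", "1"): 0.936,
    ("III", "2"): 0.963,
    ("III", "3"): 0.941,
    ("III", "4"): 0.932,
    ("III", "5"): 0.939,
    ("III", "6"): 0.940,
    ("III", "7"): 0.934,
    ("III", "8"): 0.962,
    ("III", "9"): 0.919,
    ("III", "10"): 0.932,
    ("IV", "1"): 1.286,
    ("IV", "2"): 1.200,
    ("IV", "3"): 1.186,
    ("V", "1"): 0.876,
    ("V", "2"): 0.782,
    ("V", "3"): 0.821,
    ("VI", "1"): 0.457,
    ("VI", "2"): 0.466,
    ("VI", "3"): 0.438,
    ("VI", "4"): 0.508,
}


def loo_intensity_from_table(layer: str, sample: str) -> float:
    """Leave-one-out pooled intensity recomputed from the sample table.

    Sums the synapse counts of every other sample of the same layer and
    divides by the sum of their volumes (the volume-weighted aggregation of
    per-sample densities). Full precision; round at reporting time.
    """
    df = sample_table()
    rest = df[(df.layer == layer) & (df["sample"] != sample)]
    if rest.empty:
        raise ValueError(f"layer {layer!r} has no other samples than {sample!r}")
    return float(rest.n_synapses.sum() / rest.volume_um3.sum())
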