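"""Layer density comparison by fixed-box subsampling and rank-based tests.

Per-sample windows differ in size, so densities are compared on equal
footing by drawing a fixed-volume box (the componentwise minimum of all
sample windows) at random locations inside randomly chosen samples of each
layer, n_rep times per layer. The resulting per-layer density draws are
compared with the Kruskal-Wallis test followed by pairwise Mann-Whitney
tests with Bonferroni adjustment. A Levene homoscedasticity check is
provided report-only (its failure is what motivates the rank-based route);
the pipeline always proceeds rank-based.

The same machinery applies unchanged to other per-layer value lists, e.g.
nearest-neighbour distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from synapstat.patterns import Box3D, StudyCollection
from synapstat.util import as_rng


@dataclass
class DensityDraws:
    """Subsample densities (per um^3) for one layer."""

    layer: str
    densities: np.ndarray
    box: Box3D
    seed: object = None

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")

    @property
    def n_rep(self) -> int:
        return self.densities.size


def min_box(study: StudyCollection) -> Box3D:
    """Componentwise minimum of all sample box sides: the largest box that
    fits inside every sample window."""
    if len(study) == 0:
        raise ValueError("empty study")
    sides = np.min([p.box.side_lengths for p in study], axis=0)
    return Box3D(side_lengths=sides)


def subsample_densities(
    study: StudyCollection,
    layer: str,
    box: Box3D,
    n_rep: int = 50,
    seed=None,
) -> DensityDraws:
    """n_rep density draws for one layer with a fixed subsampling box.

    Each draw picks a sample uniformly at random (with replacement), places
    the box uniformly over the valid placements inside that sample's
    window, and counts centroids in the half-open box.
    """
    rng = as_rng(seed)
    samples = study.by_layer(layer)
    for p in samples:
        if np.any(box.side_lengths > p.box.side_lengths):
            raise ValueError(
                f"subsampling box does not fit inside sample "
                f"({p.layer!r}, {p.sample_id!r})"
            )
    densities = np.empty(n_rep)
    vol = box.volume_um3
    for r in range(n_rep):
        p = samples[rng.integers(len(samples))]
        slack = p.box.side_lengths - box.side_lengths
        origin = p.box.origin + rng.random(3) * slack
        inside = Box3D(side_lengths=box.side_lengths, origin=origin)
        densities[r] = int(np.count_nonzero(inside.contains(p.coords))) / vol
    return DensityDraws(layer=layer, densities=densities, box=box, seed=seed)


def _as_groups(draws) -> tuple[list[str], list[np.ndarray]]:
    labels, values = [], []
    for d in draws:
        if isinstance(d, DensityDraws):
            labels.append(d.layer)
            values.append(d.densities)
        else:  # (label, values) pair
            labels.append(d[0])
            values.append(np.asarray(d[1], dtype=float))
    return labels, values


def kruskal_wallis(draws) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    labels, values = _as_groups(draws)
    if len(values) < 2 or any(v.size < 2 for v in values):
        raise ValueError("need at least 2 groups with at least 2 values each")
    if all(np.array_equal(v, values[0]) for v in values[1:]):
        # scipy raises when all values are identical; the test statistic
        # degenerates to 0 and carries no evidence against the null
        return 0.0, 1.0
    h, p = stats.kruskal(*values)
    return float(h), float(p)


def pairwise_mw_bonferroni(draws, method: str = "auto") -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests, Bonferroni-adjusted.

    Raw p-values are multiplied by the number of pairs and capped at 1.
    ``method='auto'`` uses the exact null distribution for small groups
    (n <= 8, no ties) and the tie-corrected normal approximation otherwise.
    """
    labels, values = _as_groups(draws)
    g = len(values)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n_pairs = g * (g - 1) // 2
    mat = pd.DataFrame(np.ones((g, g)), index=labels, columns=labels)
    for i in range(g):
        for j in range(i + 1, g):
            if np.array_equal(values[i], values[j]):
                p = 1.0
            else:
                use = method
                if method == "auto":
                    small = max(values[i].size, values[j].size) <= 8
                    ties = np.intersect1d(values[i], values[j]).size > 0
                    use = "exact" if small and not ties else "asymptotic"
                _, p = stats.mannwhitneyu(
                    values[i], values[j], alternative="two-sided", method=use
                )
            adj = min(1.0, float(p) * n_pairs)
            mat.iloc[i, j] = adj
            mat.iloc[j, i] = adj
    return mat


def levene_check(draws) -> tuple[float, float]:
    """Report-only homoscedasticity check (Levene's W and p-value)."""
    _, values = _as_groups(draws)
    w, p = stats.levene(*values)
    return float(w), float(p)
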