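import itertools

import numpy as np
import pytest

import synapstat as ss
from synapstat.density import levene_check
from synapstat.reference import LAYER_MEANS


def exact_mw_p(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of rank splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0
    n_a = len(a)

    def u_of(idx):
        r_a = ranks[list(idx)].sum()
        u1 = r_a - n_a * (n_a + 1) / 2
        return min(u1, len(a) * len(b) - u1)

    observed = u_of(range(n_a))
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        extreme += u_of(idx) <= observed
    return extreme / total


class TestMinBox:
    def test_single_sample(self, cube):
        study = ss.StudyCollection(
            [ss.PointPattern3D(box=cube, coords=[[1, 1, 1]], layer="I", sample_id="1")]
        )
        np.testing.assert_array_equal(ss.min_box(study).side_lengths, cube.side_lengths)

    def test_componentwise_minimum(self):
        b1 = ss.Box3D([10.0, 20.0, 30.0])
        b2 = ss.Box3D([15.0, 5.0, 30.0])
        study = ss.StudyCollection(
            [
                ss.PointPattern3D(box=b1, coords=[[1, 1, 1]], layer="I", sample_id="1"),
                ss.PointPattern3D(box=b2, coords=[[1, 1, 1]], layer="I", sample_id="2"),
            ]
        )
        np.testing.assert_array_equal(ss.min_box(study).side_lengths, [10.0, 5.0, 30.0])

    def test_fits_every_sample_box(self, default_study):
        box = ss.min_box(default_study)
        for p in default_study:
            assert np.all(box.side_lengths <= p.box.side_lengths)

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            ss.min_box(ss.StudyCollection([]))


class TestSubsampleDensities:
    def test_full_box_returns_sample_density(self, cube, rng):
        p = ss.PointPattern3D(
            box=cube, coords=rng.random((37, 3)) * 1000, layer="I", sample_id="1"
        )
        study = ss.StudyCollection([p])
        draws = ss.subsample_densities(study, "I", cube, n_rep=10, seed=0)
        np.testing.assert_allclose(draws.densities, p.intensity)

    def test_empty_pattern_gives_zero_draws(self, cube):
        p = ss.PointPattern3D(
            box=cube, coords=np.empty((0, 3)), layer="I", sample_id="1"
        )
        study = ss.StudyCollection([p])
        draws = ss.subsample_densities(study, "I", cube, n_rep=5, seed=0)
        assert (draws.densities == 0).all()

    def test_unbiased_for_homogeneous_layer(self):
        lam = 1.0
        box = ss.Box3D([4000.0, 4000.0, 4000.0])
        rng = np.random.default_rng(4)
        pats = [
            ss.simulate_csr(box, lam, seed=rng, fixed_n=False).with_metadata(
                layer="X", sample_id=str(i)
            )
            for i in range(3)
        ]
        study = ss.StudyCollection(pats)
        sub = ss.Box3D([2000.0, 2000.0, 2000.0])
        draws = ss.subsample_densities(study, "X", sub, n_rep=500, seed=11)
        se = draws.densities.std(ddof=1) / np.sqrt(draws.n_rep)
        assert abs(draws.densities.mean() - lam) <= 3 * se

    def test_oversized_box_rejected(self, cube, rng):
        p = ss.PointPattern3D(
            box=cube, coords=rng.random((5, 3)) * 1000, layer="I", sample_id="1"
        )
        study = ss.StudyCollection([p])
        big = ss.Box3D([2000.0, 100.0, 100.0])
        with pytest.raises(ValueError):
            ss.subsample_densities(study, "I", big, n_rep=2, seed=0)

    def test_reproducible_under_seed(self, default_study):
        box = ss.min_box(default_study)
        a = ss.subsample_densities(default_study, "III", box, n_rep=20, seed=8)
        b = ss.subsample_densities(default_study, "III", box, n_rep=20, seed=8)
        np.testing.assert_array_equal(a.densities, b.densities)


class TestRankTests:
    def test_kruskal_wallis_hand_value(self):
        h, p = ss.kruskal_wallis([("a", [1.0, 2.0]), ("b", [3.0, 4.0])])
        assert h == pytest.approx(2.4)

    def test_identical_groups_are_null(self):
        h, p = ss.kruskal_wallis([("a", [1.0, 2.0]), ("b", [1.0, 2.0])])
        assert h == 0.0
        assert p == 1.0

    def test_mann_whitney_exact_third(self):
        mat = ss.pairwise_mw_bonferroni([("a", [1.0, 2.0]), ("b", [3.0, 4.0])])
        assert mat.loc["a", "b"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mann_whitney_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 7)
        mat = ss.pairwise_mw_bonferroni([("a", a), ("b", b)], method="exact")
        assert mat.loc["a", "b"] == pytest.approx(exact_mw_p(a, b))

    def test_group_against_itself(self):
        v = [1.0, 2.0, 3.0]
        mat = ss.pairwise_mw_bonferroni([("a", v), ("b", v)])
        assert mat.loc["a", "b"] == 1.0

    def test_adjustment_caps_and_dominates_raw(self, rng):
        groups = [(str(i), rng.normal(i * 0.1, 1, 20)) for i in range(4)]
        adjusted = ss.pairwise_mw_bonferroni(groups)
        from scipy.stats import mannwhitneyu

        for i in range(4):
            for j in range(i + 1, 4):
                _, raw = mannwhitneyu(
                    groups[i][1], groups[j][1], alternative="two-sided"
                )
                assert raw <= adjusted.iloc[i, j] <= 1.0


@pytest.fixture(scope="module")
def draws(default_study):
    box = ss.min_box(default_study)
    rng = np.random.default_rng(21)
    return [
        ss.subsample_densities(default_study, lay, box, n_rep=50, seed=rng)
        for lay in default_study.layers
    ]


class TestLayerComparisonPipeline:

    def test_layers_significantly_different(self, draws):
        """The six layers differ strongly in density (study found p<=2.2e-16)."""
        _, p = ss.kruskal_wallis(draws)
        assert p < 1e-3

    def test_similar_layers_not_flagged(self):
        """Two layers generated at one intensity stay non-significant."""
        rng = np.random.default_rng(33)
        pats = []
        for lay, sides in (("A", [6000.0, 5200.0, 4400.0]), ("B", [5400.0, 6100.0, 4800.0])):
            for i in range(3):
                box = ss.Box3D(np.asarray(sides) + 200.0 * i)
                pats.append(
                    ss.simulate_csr(box, 0.8, seed=rng).with_metadata(
                        layer=lay, sample_id=str(i)
                    )
                )
        study = ss.StudyCollection(pats)
        draws = [
            ss.subsample_densities(study, lay, ss.min_box(study), n_rep=50, seed=rng)
            for lay in ("A", "B")
        ]
        mat = ss.pairwise_mw_bonferroni(draws)
        assert mat.loc["A", "B"] > 0.05

    def test_levene_report_only(self, draws):
        w, p = levene_check(draws)
        assert w >= 0 and 0 <= p <= 1

    def test_same_machinery_on_nearest_neighbor_distances(self, default_study):
        groups = [
            (lay, np.concatenate([
                ss.nearest_neighbor_distances(p) for p in default_study.by_layer(lay)
            ]))
            for lay in ("IV", "VI")
        ]
        h, p = ss.kruskal_wallis(groups)
        # sparser layer VI has clearly larger spacing than dense layer IV
        assert p < 1e-6
        assert groups[1][1].mean() > groups[0][1].mean()
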