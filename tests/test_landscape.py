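"""Potential evaluation, basin classification, passes, clustering, embedding."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polariscape as ps
from polariscape.landscape import cluster_composition

from conftest import random_landscape


class TestPotential:
    def test_zero_at_centers_positive_elsewhere(self, double_well):
        assert ps.potential(double_well, (0.0, 0.0)) == 0.0
        assert ps.potential(double_well, (1.0, 0.0)) == 0.0
        assert ps.potential(double_well, (0.3, 0.4)) > 0

    def test_single_well_values(self):
        ls = ps.Landscape(labels=("w",), centers=[[1.0, 1.0]], steepness=[2.0])
        assert ps.potential(ls, (1.0, 1.0)) == 0.0
        assert ps.potential(ls, (2.0, 1.0)) == pytest.approx(2.0)

    def test_symmetric_tie(self):
        ls = ps.Landscape(labels=("a", "b"), centers=[[0, 0], [2, 0]], steepness=[1, 1])
        assert ps.potential(ls, (1.0, 0.0)) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        ls = random_landscape(rng)
        pts = rng.uniform(-5, 5, size=(50, 2))
        assert np.all(ps.potential(ls, pts) >= 0)

    def test_validation(self):
        with pytest.raises(ValueError, match="steepness"):
            ps.Landscape(labels=("a",), centers=[[0, 0]], steepness=[-1.0])
        with pytest.raises(ValueError, match="distinct"):
            ps.Landscape(labels=("a", "b"), centers=[[0, 0], [0, 0]], steepness=[1, 1])
        with pytest.raises(ValueError, match="unique"):
            ps.Landscape(labels=("a", "a"), centers=[[0, 0], [1, 0]], steepness=[1, 1])


class TestClassifyPoint:
    def test_center_maps_to_own_basin(self, reference_landscape):
        for i in range(reference_landscape.n):
            assert ps.classify_point(reference_landscape, reference_landscape.centers[i]) == i

    def test_tie_breaks_to_lowest_index(self):
        ls = ps.Landscape(labels=("a", "b"), centers=[[0, 0], [2, 0]], steepness=[1, 1])
        assert ps.classify_point(ls, (1.0, 0.0)) == 0

    def test_weighted_classification(self):
        # a=(4,1): the midpoint-ish point belongs to the shallow well
        ls = ps.Landscape(labels=("a", "b"), centers=[[0, 0], [3, 0]], steepness=[4, 1])
        assert ps.classify_point(ls, (1.5, 0.0)) == 1

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        ls = random_landscape(rng)
        pts = rng.uniform(-4, 4, size=(100, 2))
        idx = ps.classify_point(ls, pts)
        assert idx.shape == (100,)
        assert np.all((0 <= idx) & (idx < ls.n))


def brute_force_pass(ls, i, j, extent=8.0, n=1200):
    """Oracle: dense-grid minimum of F on the i/j boundary band."""
    xs = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    diff = pts[:, None, :] - ls.centers[None, :, :]
    vals = np.einsum("ijk,ijk->ij", diff, diff) * ls.steepness
    order = np.argsort(vals, axis=1)
    first, second = order[:, 0], order[:, 1]
    v1 = vals[np.arange(len(pts)), first]
    v2 = vals[np.arange(len(pts)), second]
    h = xs[1] - xs[0]
    # grid cells straddling the i-j boundary: the two smallest wells are {i,j}
    # and their values are nearly equal
    band = (np.minimum(first, second) == min(i, j)) & (
        np.maximum(first, second) == max(i, j)
    ) & (v2 - v1 < 6.0 * h)
    if not np.any(band):
        return None
    k = np.argmin(np.where(band, v1, np.inf))
    return pts[k], v1[k]


class TestFindPasses:
    def test_symmetric_double_well(self):
        ls = ps.make_double_well(a=(1.0, 1.0), separation=2.0)
        (p,) = ps.find_passes(ls)
        assert p.height == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(p.location, [1.0, 0.0], atol=1e-6)

    def test_weighted_double_well(self):
        # boundary crosses the segment at distance D*sqrt(a_j)/(sqrt(a_i)+sqrt(a_j))
        ls = ps.make_double_well(a=(1.0, 4.0), separation=3.0)
        (p,) = ps.find_passes(ls)
        assert np.allclose(p.location, [2.0, 0.0], atol=1e-6)
        assert p.height == pytest.approx(4.0, abs=1e-6)

    def test_pass_heights_nonnegative(self, reference_landscape):
        for p in ps.find_passes(reference_landscape):
            assert p.height > 0

    def test_matches_brute_force_on_random_landscapes(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(20):
            ls = random_landscape(rng)
            passes = {p.pair: p for p in ps.find_passes(ls)}
            for (i, j), p in passes.items():
                oracle = brute_force_pass(ls, i, j)
                if oracle is None:
                    continue
                _, h_oracle = oracle
                # the band oracle sits within O(grid step * |grad F|) of the
                # true boundary minimum, on either side
                assert abs(p.height - h_oracle) < 0.05 * (1.0 + h_oracle)
                checked += 1
        assert checked >= 20

    def test_monotone_in_steepness(self):
        heights = []
        for a1 in [0.5, 1.0, 2.0, 4.0]:
            ls = ps.make_double_well(a=(a1, 1.0), separation=2.0)
            heights.append(ps.find_passes(ls)[0].height)
        assert all(h2 > h1 for h1, h2 in zip(heights, heights[1:]))

    def test_single_basin_rejected(self, single_well):
        with pytest.raises(ValueError):
            ps.find_passes(single_well)


class TestClusterCenters:
    def test_two_separated_pairs(self):
        ls = ps.Landscape(
            labels=("a", "b", "c", "d"),
            centers=[[0, 0], [0.5, 0], [10, 0], [10.5, 0]],
            steepness=[1, 1, 1, 1],
        )
        assign = ps.cluster_centers(ls)
        assert len(set(assign)) == 2
        assert assign[0] == assign[1] and assign[2] == assign[3]
        assert assign[0] != assign[2]

    def test_reference_landscape_five_clusters(self, reference_landscape):
        assign = ps.cluster_centers(reference_landscape)
        comp = cluster_composition(reference_landscape, assign)
        assert len(comp) == 5
        anti = [c for c, labs in comp.items() if "M1" in labs]
        assert len(anti) == 1
        assert set(comp[anti[0]]) == {"M1", "M1M2d"}

    def test_forced_cluster_count(self, reference_landscape):
        assign = ps.cluster_centers(reference_landscape, n_clusters=3)
        assert len(set(assign)) == 3


class TestBuildLandscape:
    def _attractor(self, phenotype, fraction):
        return ps.Attractor(
            states=((0, 0),), basin_size=1, basin_fraction=fraction,
            nodes=("x", "y"), phenotype=phenotype,
        )

    def test_two_phenotype_proportional_depths(self):
        atts = [self._attractor("P", 0.75), self._attractor("Q", 0.25)]
        coords = np.array([[0.0, 0.0], [2.0, 0.0]])
        ls = ps.build_landscape(atts, coords, depth_rule="proportional", scale=4.0)
        by = dict(zip(ls.labels, ls.steepness))
        assert by["P"] == pytest.approx(3.0)
        assert by["Q"] == pytest.approx(1.0)

    def test_single_phenotype_degenerate(self):
        ls = ps.build_landscape([self._attractor("P", 1.0)], np.array([[1.0, 2.0]]),
                                scale=2.0)
        assert ls.n == 1
        assert ls.steepness[0] == pytest.approx(2.0)

    def test_centroid_center_rule(self):
        atts = [self._attractor("P", 0.3), self._attractor("P", 0.3),
                self._attractor("Q", 0.4)]
        coords = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0]])
        ls = ps.build_landscape(atts, coords)
        assert np.allclose(ls.center("P"), [1.0, 1.0])

    def test_unlabeled_attractor_rejected(self):
        a = ps.Attractor(states=((0,),), basin_size=1, basin_fraction=1.0, nodes=("x",))
        with pytest.raises(ValueError, match="labeled"):
            ps.build_landscape([a], np.array([[0.0, 0.0]]))


class TestEmbedAttractors:
    def _attractors(self, toy3):
        return ps.find_attractors(toy3)

    def test_shape_and_determinism(self, toy3):
        atts = self._attractors(toy3)
        cfg = ps.EmbeddingConfig(perplexity=1.5, seed=3)
        c1 = ps.embed_attractors(atts, cfg)
        c2 = ps.embed_attractors(atts, cfg)
        assert c1.shape == (3, 2)
        assert np.array_equal(c1, c2)

    def test_perplexity_validated(self, toy3):
        atts = self._attractors(toy3)
        with pytest.raises(ValueError, match="perplexity"):
            ps.embed_attractors(atts, ps.EmbeddingConfig(perplexity=10.0))

    def test_identical_states_embed_close(self):
        # two identical mean bit vectors should sit closer than the median pair
        base = ps.Attractor(states=((1, 0, 1, 0),), basin_size=1, basin_fraction=0.2,
                            nodes=("a", "b", "c", "d"))
        others = [
            ps.Attractor(states=(s,), basin_size=1, basin_fraction=0.2,
                         nodes=("a", "b", "c", "d"))
            for s in [(0, 1, 0, 1), (1, 1, 1, 1), (0, 0, 0, 0)]
        ]
        atts = [base, base] + others
        coords = ps.embed_attractors(atts, ps.EmbeddingConfig(perplexity=2.0, seed=0))
        d_twin = np.linalg.norm(coords[0] - coords[1])
        dists = [
            np.linalg.norm(coords[i] - coords[j])
            for i in range(5) for j in range(i + 1, 5)
        ]
        assert d_twin <= np.median(dists)
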