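"""KNN enrichment: oracle equivalence, symmetry, subsampling, island gates."""

import numpy as np
import pytest

import cytosar as cs
from cytosar.trex import TrexConfig, TrexResult, knn_enrichment, knn_neighbors

from conftest import make_table


def brute_force_fractions(coords: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Independent oracle: all-pairs distances, ties broken by index."""
    n = len(coords)
    is_test = labels == "test"
    out = np.empty(n)
    for i in range(n):
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        order = sorted(range(n), key=lambda j: (d[j], j))
        nbrs = [j for j in order if j != i][:k]
        out[i] = np.mean(is_test[nbrs])
    return out


class TestKnnEnrichment:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(12)
        for trial in range(10):
            n = int(rng.integers(50, 301))
            k = int(rng.integers(3, 30))
            coords = rng.normal(size=(n, 2))
            labels = np.where(rng.random(n) < 0.5, "test", "reference")
            if len(set(labels)) < 2:
                continue
            res = knn_enrichment(coords, labels, TrexConfig(k=k))
            oracle = brute_force_fractions(coords, labels, k)
            np.testing.assert_array_equal(res.fraction_from_test, oracle)

    def test_boundary_arithmetic_at_default_cutoffs(self):
        # a cell with 57 of its 60 nearest neighbors from the test sample
        # sits exactly at fraction 0.95 and is a red hotspot
        frac = 57 / 60
        assert frac == pytest.approx(0.95)
        res = TrexResult(np.array([frac]), np.array(["red"], dtype=object),
                         {"test": 1, "reference": 1}, TrexConfig())
        assert res.n_red == 1

    def test_interleaved_lattice_has_no_hotspots(self):
        # perfectly alternating 50/50 grid: every neighborhood is mixed
        xs, ys = np.meshgrid(np.arange(30), np.arange(30))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        labels = np.where((xs + ys).ravel() % 2 == 0, "test", "reference")
        res = knn_enrichment(coords, labels, TrexConfig(k=8))
        assert np.all(np.abs(res.fraction_from_test - 0.5) <= 0.25)
        assert res.degree_of_difference == 0.0

    def test_label_swap_maps_fraction_to_complement(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(200, 2))
        labels = np.where(rng.random(200) < 0.5, "test", "reference")
        swapped = np.where(labels == "test", "reference", "test")
        a = knn_enrichment(coords, labels, TrexConfig(k=15))
        b = knn_enrichment(coords, swapped, TrexConfig(k=15))
        np.testing.assert_allclose(a.fraction_from_test, 1.0 - b.fraction_from_test)
        assert a.degree_of_difference == b.degree_of_difference

    def test_single_label_input_rejected(self):
        coords = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError, match="test"):
            knn_enrichment(coords, np.array(["test"] * 50), TrexConfig(k=5))

    def test_k_must_be_smaller_than_n(self):
        coords = np.zeros((5, 2))
        with pytest.raises(ValueError, match="k="):
            knn_neighbors(coords, 5)


class TestDegreeOfDifference:
    def test_printed_formula(self):
        hotspot = np.array(["red"] * 150 + ["blue"] * 50 + ["none"] * 800,
                           dtype=object)
        res = TrexResult(np.zeros(1000), hotspot, {}, TrexConfig())
        assert cs.degree_of_difference(res) == pytest.approx(0.20)

    def test_extremes(self):
        none = TrexResult(np.zeros(10), np.array(["none"] * 10, dtype=object),
                          {}, TrexConfig())
        assert cs.degree_of_difference(none) == 0.0
        full = TrexResult(np.zeros(10), np.array(["red"] * 5 + ["blue"] * 5,
                                                 dtype=object), {}, TrexConfig())
        assert cs.degree_of_difference(full) == 1.0


class TestEqualSubsample:
    def _groups(self, sizes):
        groups = {}
        for name, n in sizes.items():
            rng = np.random.default_rng(abs(hash(name)) % 2**31)
            groups[name] = make_table({"m": rng.normal(size=n)})
        return groups

    def test_exact_equal_counts(self):
        out = cs.equal_subsample(self._groups({"a": 1500, "b": 2000, "c": 1200}),
                                 1000, seed=0)
        counts = out.annotations["group"].value_counts()
        assert (counts == 1000).all() and len(counts) == 3

    def test_fixed_seed_reproduces_sample(self):
        groups = self._groups({"a": 500, "b": 700})
        a = cs.equal_subsample(groups, 300, seed=5)
        b = cs.equal_subsample(groups, 300, seed=5)
        np.testing.assert_array_equal(a.data["m"], b.data["m"])

    def test_small_group_lowers_target_for_all(self):
        out = cs.equal_subsample(self._groups({"a": 100, "b": 2000}), 500, seed=1)
        counts = out.annotations["group"].value_counts()
        assert (counts == 100).all()

    def test_empty_group_rejected(self):
        groups = self._groups({"a": 100})
        groups["empty"] = make_table({"m": np.empty(0)})
        with pytest.raises(ValueError, match="empty"):
            cs.equal_subsample(groups, 10, seed=0)


class TestEmbedding:
    def test_separated_clusters_stay_separated(self, panel):
        a = cs.generate_well_events(panel, cs.EffectSignature(), 300, seed=1)
        shifts = {m: 4.0 for m in panel.markers}
        b = cs.generate_well_events(panel, cs.EffectSignature(shift=shifts), 300,
                                    seed=2)
        both = cs.EventTable.concat([cs.arcsinh_scale(a, panel.cofactors),
                                     cs.arcsinh_scale(b, panel.cofactors)])
        coords = cs.embed(both, panel.markers,
                          cs.EmbedParams(perplexity=30, max_iter=260), seed=0)
        from sklearn.metrics import silhouette_score

        labels = np.array([0] * 300 + [1] * 300)
        assert silhouette_score(coords.coords, labels) > 0.5

    def test_duplicate_rows_yield_finite_coords(self):
        tab = make_table({"m1": np.ones(120), "m2": np.zeros(120)})
        coords = cs.embed(tab, ["m1", "m2"],
                          cs.EmbedParams(perplexity=10, max_iter=260), seed=0)
        assert np.isfinite(coords.coords).all()

    def test_too_few_events_for_perplexity(self):
        tab = make_table({"m1": np.arange(50.0)})
        with pytest.raises(ValueError, match="perplexity"):
            cs.embed(tab, ["m1"], cs.EmbedParams(perplexity=60), seed=0)

    def test_provenance_recorded(self):
        tab = make_table({"m1": np.random.default_rng(0).normal(size=200)})
        coords = cs.embed(tab, ["m1"], cs.EmbedParams(perplexity=10, max_iter=260),
                          seed=7)
        assert coords.provenance["seed"] == 7
        assert coords.provenance["method"] == "tsne"


class TestIslandQuantify:
    def test_gate_containing_all_points(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-1, 1, size=(100, 2))
        gate = [(-2, -2), (2, -2), (2, 2), (-2, 2)]
        out = cs.island_quantify(coords, gate, ["g"] * 100)
        assert out["g"] == 100.0

    def test_unit_square_hand_count(self):
        pts = np.array([[0.5, 0.5], [1.5, 0.5], [0.25, 0.75], [-0.1, 0.2],
                        [0.9, 0.99]])
        gate = [(0, 0), (1, 0), (1, 1), (0, 1)]
        out = cs.island_quantify(pts, gate, ["a"] * 5)
        assert out["a"] == pytest.approx(100 * 3 / 5)

    def test_empty_group_reported_missing(self):
        coords = np.zeros((3, 2)) + 0.5
        gate = [(0, 0), (1, 0), (1, 1), (0, 1)]
        out = cs.island_quantify(coords, gate, ["a"] * 3, all_groups=["a", "b"])
        assert out["b"] is None
        assert out["a"] == 100.0

    def test_degenerate_and_self_intersecting_polygons_rejected(self):
        coords = np.zeros((2, 2))
        with pytest.raises(ValueError, match="3 vertices"):
            cs.island_quantify(coords, [(0, 0), (1, 1)], ["a", "a"])
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError, match="simple"):
            cs.island_quantify(coords, bowtie, ["a", "a"])


def test_vehicle_null_self_comparison_small_scale(panel):
    """Splitting one homogeneous sample randomly in two gives D < 1% for
    every seed (small-scale version of the vehicle-vs-vehicle null)."""
    n = 2000
    for seed in range(10):
        tab = cs.generate_well_events(panel, cs.EffectSignature(), n,
                                      seed=200 + seed)
        scaled = cs.arcsinh_scale(tab, panel.cofactors)
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random(n) < 0.5, "test", "reference")
        coords = cs.embed(scaled, panel.markers,
                          cs.EmbedParams(perplexity=30, max_iter=260), seed=seed)
        res = cs.knn_enrichment(coords, labels, cs.TrexConfig())
        assert res.degree_of_difference < 0.01
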