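"""Motional-class decomposition: error filter, class-count selection,
k-means centers/boundaries, and residue-type composition."""

import numpy as np
import pytest

from methyldyn.classify import (
    class_composition,
    classify_set,
    filter_by_error,
    kmeans_classes,
    select_class_count,
)
from methyldyn.exceptions import InsufficientDataError, MethylDynError
from methyldyn.probes import MethylProbe

from conftest import make_probe, make_set


class TestErrorFilter:
    def test_boundary_is_inclusive(self):
        opset = make_set([0.2, 0.4, 0.6], errors=[0.05, 0.10, 0.11])
        kept, removed = filter_by_error(opset, max_error=0.1)
        assert [e.error for e in kept] == [0.05, 0.10]
        assert removed == 1

    def test_zero_errors_pass_unchanged(self):
        opset = make_set([0.2, 0.4, 0.6])
        kept, removed = filter_by_error(opset)
        assert kept == opset
        assert removed == 0

    def test_high_uncertainty_entry_excluded_from_statistics(self):
        # mirrors a rigid probe measured at 0.88 +/- 0.11: too uncertain for
        # the class histogram even though its value is plausible
        opset = make_set([0.88, 0.14, 0.36], errors=[0.11, 0.02, 0.03])
        kept, _ = filter_by_error(opset, max_error=0.1)
        assert 0.88 not in kept.values


class TestSelectClassCount:
    def test_single_tight_component(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.4, 0.03, size=100)
        k, scores = select_class_count(values, seed=0)
        assert k == 1
        assert scores[1] < scores[3]

    def test_three_well_separated_components(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = np.concatenate(
                [rng.normal(c, 0.04, size=50) for c in (0.21, 0.40, 0.65)]
            )
            k, _ = select_class_count(values, seed=seed)
            hits += k == 3
        assert hits >= 9

    def test_overlapping_components_collapse_to_one(self):
        # data from one Gaussian: a duplicate-center k=2 model is penalized
        rng = np.random.default_rng(1)
        values = rng.normal(0.5, 0.05, size=120)
        k, _ = select_class_count(values, seed=1)
        assert k == 1

    def test_needs_enough_values(self):
        with pytest.raises(InsufficientDataError):
            select_class_count([0.2, 0.4, 0.6])


class TestKmeansClasses:
    def test_exact_two_cluster_geometry(self):
        model = kmeans_classes([0.1, 0.1, 0.1, 0.9, 0.9, 0.9], k=2)
        np.testing.assert_allclose(model.centers, [0.1, 0.9], atol=1e-12)
        np.testing.assert_allclose(model.boundaries, [0.5], atol=1e-12)

    def test_permutation_invariant_and_deterministic(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(c, 0.05, 60) for c in (0.2, 0.5)])
        values = np.clip(values, 0.01, 0.99)
        a = kmeans_classes(values, k=2, seed=7)
        b = kmeans_classes(rng.permutation(values), k=2, seed=7)
        c = kmeans_classes(values, k=2, seed=7)
        np.testing.assert_allclose(a.centers, b.centers, atol=1e-12)
        np.testing.assert_array_equal(a.assignments, c.assignments)

    def test_class_sizes_conserve_probe_count(self):
        rng = np.random.default_rng(3)
        values = np.clip(rng.normal(0.4, 0.15, size=87), 0.01, 0.99)
        model = kmeans_classes(values, k=3)
        assert model.class_sizes().sum() == 87

    def test_boundaries_separate_assignments(self):
        rng = np.random.default_rng(4)
        values = np.clip(rng.normal(0.4, 0.15, size=100), 0.01, 0.99)
        model = kmeans_classes(values, k=3)
        edges = np.concatenate([[-np.inf], model.boundaries, [np.inf]])
        for v, ci in zip(model.values, model.assignments):
            assert edges[ci] <= v <= edges[ci + 1]

    def test_center_recovery_on_separated_mixtures(self):
        # separation >= 3 sigma: centers recovered within 3*sigma/sqrt(n_comp)
        sigma, n_comp = 0.04, 60
        centers = np.array([0.20, 0.40, 0.62])
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.concatenate(
                [rng.normal(c, sigma, size=n_comp) for c in centers]
            )
            model = kmeans_classes(np.clip(values, 0.0, 1.0), k=3, seed=seed)
            # allow the systematic truncation shift of k-means on overlapping
            # tails in addition to the sampling term
            tol = 3 * sigma / np.sqrt(n_comp) + 0.4 * sigma
            assert np.max(np.abs(model.centers - centers)) < tol

    def test_k_larger_than_distinct_values_rejected(self):
        with pytest.raises(MethylDynError, match="distinct"):
            kmeans_classes([0.1, 0.1, 0.9], k=3)

    def test_membrane_protein_band_labels(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(c, 0.04, 40) for c in (0.21, 0.36, 0.55)])
        model = kmeans_classes(np.clip(values, 0.0, 1.0), k=3)
        assert model.labels == ["J'", "J", "alpha"]

    def test_soluble_protein_band_labels(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(c, 0.04, 40) for c in (0.35, 0.6, 0.85)])
        model = kmeans_classes(np.clip(values, 0.0, 1.0), k=3)
        assert model.labels == ["J", "alpha", "omega"]

    def test_two_class_labels_warn_about_taxonomy(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            kmeans_classes([0.1, 0.12, 0.7, 0.72], k=2)

    def test_out_of_range_values_clipped_and_flagged(self):
        model = kmeans_classes([0.1, 0.2, 1.05, 0.9], k=2)
        assert model.clipped.tolist() == [False, False, True, False]
        assert model.values.max() == 1.0


class TestClassComposition:
    def test_all_valine_has_zero_enrichment(self):
        probes = [make_probe(i, "VAL") for i in range(1, 7)]
        model = kmeans_classes([0.1, 0.12, 0.1, 0.9, 0.88, 0.9], k=2)
        comp = class_composition(model, probes)
        assert (comp["frac_V"] == 1.0).all()
        assert (comp["enrich_V"] == 0.0).all()

    def test_planted_composition_recovered(self):
        # lowest band drawn 3:1 MLI:V, the others 1:1
        rng = np.random.default_rng(8)
        n = 200
        comps = rng.integers(0, 3, size=n)
        centers = np.array([0.21, 0.40, 0.62])
        values = np.clip(centers[comps] + rng.normal(0, 0.04, n), 0.0, 1.0)
        types = []
        for c in comps:
            p_mli = 0.75 if c == 0 else 0.5
            types.append("LEU" if rng.random() < p_mli else "VAL")
        probes = [make_probe(i + 1, t) for i, t in enumerate(types)]
        model = kmeans_classes(values, k=3, seed=8)
        comp = class_composition(model, probes)
        n_low = comp.loc["J'", "n"]
        ci = 3 * np.sqrt(0.75 * 0.25 / n_low)
        assert abs(comp.loc["J'", "frac_MLI"] - 0.75) < ci + 0.05
        assert comp.loc["J'", "enrich_MLI"] > 0

    def test_probe_count_mismatch_rejected(self):
        model = kmeans_classes([0.1, 0.9], k=2)
        with pytest.raises(MethylDynError):
            class_composition(model, [make_probe(1)])


class TestClassifySet:
    def test_filter_then_cluster_pipeline(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(c, 0.04, 40) for c in (0.21, 0.40, 0.60)])
        errors = np.full_like(values, 0.02)
        errors[:5] = 0.5  # junk entries that must not influence the model
        opset = make_set(np.clip(values, 0.01, 0.99), errors=errors)
        with pytest.warns(UserWarning, match="removed"):
            model, filtered = classify_set(opset, k=3)
        assert len(filtered) == len(values) - 5
        assert model.class_sizes().sum() == len(filtered)
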