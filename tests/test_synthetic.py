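"""Cohort generator: exact apportionment, determinism, pairing, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xmodal.errors import ConfigError
from xmodal.synthetic import (CLASSES, CohortSpec, cohort_summary, generate_cohort,
                              largest_remainder, paired_subset, render_slide,
                              table1_spec, write_cohort)


class TestApportionment:
    def test_default_composition_matches_printed_counts(self):
        counts = CohortSpec().class_counts()
        assert counts == {"chondroid_high": 13, "chondroid_low": 68, "mimic": 107}

    def test_default_cohort_percentages(self, default_cohort):
        s = cohort_summary(default_cohort)
        assert s["pct_tumor"] == 43
        assert s["pct_high_of_tumor"] == 16
        assert s["n_mimic"] == 107 and s["n_high"] == 13 and s["n_low"] == 68

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           st.integers(3, 500))
    @settings(deadline=None, max_examples=60)
    def test_counts_sum_to_n_for_any_probs(self, raw, n):
        probs = np.array(raw) / np.sum(raw)
        counts = largest_remainder(probs, n)
        assert counts.sum() == n
        assert (counts >= 0).all()
        # never off by more than one from the exact quota
        assert np.all(np.abs(counts - probs * n) < 1.0)


class TestGeneration:
    def test_deterministic_field_by_field(self):
        a = generate_cohort(table1_spec(seed=3))
        b = generate_cohort(table1_spec(seed=3))
        for ra, rb in zip(a, b, strict=True):
            assert ra.patient_id == rb.patient_id
            assert ra.diagnosis_label == rb.diagnosis_label
            assert ra.grade_label == rb.grade_label
            assert np.array_equal(ra.radiograph_view, rb.radiograph_view)
            if ra.histology_bag is None:
                assert rb.histology_bag is None
            else:
                for pa, pb in zip(ra.histology_bag, rb.histology_bag, strict=True):
                    assert np.array_equal(pa, pb)

    def test_mimics_have_no_histology_under_default_pairing(self, default_cohort):
        for r in default_cohort:
            if r.diagnosis_label == "mimic":
                assert r.histology_bag is None
            assert r.radiograph_view is not None  # every record has a view
            assert (r.grade_label is not None) == (r.diagnosis_label == "tumor")

    def test_paired_subset_default_is_all_tumors(self, default_cohort):
        paired = paired_subset(default_cohort)
        assert len(paired) == 81
        assert all(r.diagnosis_label == "tumor" for r in paired)
        ids = [r.patient_id for r in paired]
        assert ids == sorted(ids)

    def test_paired_subset_edge_rules(self):
        none_spec = table1_spec(seed=1, pairing_rule=())
        assert paired_subset(generate_cohort(none_spec)) == []
        all_spec = table1_spec(seed=1, pairing_rule=CLASSES, n_patients=40)
        assert len(paired_subset(generate_cohort(all_spec))) == 40

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(class_probs=(0.5, 0.5, 0.1)).validate()
        with pytest.raises(ConfigError):
            CohortSpec(n_patients=2).validate()
        with pytest.raises(ConfigError):
            CohortSpec(render_mode="volumetric").validate()
        with pytest.raises(ConfigError):
            CohortSpec(bag_size_range=(5, 2)).validate()

    def test_bag_sizes_within_range(self, default_cohort):
        lo, hi = CohortSpec().bag_size_range
        for r in paired_subset(default_cohort):
            assert lo <= len(r.histology_bag) <= hi


class TestSignalStructure:
    def test_no_signal_means_identical_class_means(self):
        spec = table1_spec(seed=5, n_patients=600, signal_strength_radiograph=0.0,
                           signal_strength_histology=0.0, within_class_spread=0.0,
                           shared_axis_weight=0.0, n_nuisance_factors=0)
        cohort = generate_cohort(spec)
        by_class = {}
        for r in cohort:
            by_class.setdefault(r.class_name, []).append(r.radiograph_view)
        means = {c: np.mean(v, axis=0) for c, v in by_class.items()}
        gap = max(np.abs(means[a] - means[b]).max()
                  for a in means for b in means if a < b)
        # centroids coincide up to sampling noise ~ 1/sqrt(n_class)
        assert gap < 0.6

    def test_histology_centroid_distance_increases_with_signal(self):
        """Rank correlation of between-grade centroid distance with signal
        strength is positive across a 5-point grid (averaged over seeds)."""
        from scipy.stats import spearmanr

        grid = [0.25, 0.5, 1.0, 1.5, 2.0]
        dists = []
        for s in grid:
            per_seed = []
            for seed in (1, 2, 3):
                spec = table1_spec(seed=seed, n_patients=300,
                                   signal_strength_histology=s,
                                   n_nuisance_factors=0)
                paired = paired_subset(generate_cohort(spec))
                hi = np.mean([np.mean(r.histology_bag, axis=0)
                              for r in paired if r.grade_label == "high"], axis=0)
                lo = np.mean([np.mean(r.histology_bag, axis=0)
                              for r in paired if r.grade_label == "low"], axis=0)
                per_seed.append(np.linalg.norm(hi - lo))
            dists.append(np.mean(per_seed))
        rho, _ = spearmanr(grid, dists)
        assert rho > 0
        assert dists[-1] > dists[0]


class TestRaster:
    def test_raster_mode_shapes_and_determinism(self):
        spec = table1_spec(seed=2, n_patients=12, render_mode="raster")
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for ra, rb in zip(a, b, strict=True):
            assert ra.radiograph_view.shape == (64, 64)
            assert np.array_equal(ra.radiograph_view, rb.radiograph_view)
            if ra.histology_bag is not None:
                assert ra.histology_bag[0].shape == (32, 32, 3)

    def test_rasters_embed_class_below_the_oracle_ceiling(self):
        """Rendered radiographs carry the same latent class assignment: a
        class-mean probe on randomly projected rasters is clearly above
        chance, while never exceeding the oracle probe on the generative
        class variable itself."""
        from xmodal.evaluation import auc

        ras = generate_cohort(table1_spec(seed=9, n_patients=150, render_mode="raster"))
        y = [1 if r.diagnosis_label == "tumor" else 0 for r in ras]
        rng = np.random.default_rng(0)
        X = np.asarray([r.radiograph_view.ravel() @ rng.normal(size=(64 * 64, 32)) / 64.0
                        for r in ras])
        mu1 = X[np.array(y) == 1].mean(axis=0)
        mu0 = X[np.array(y) == 0].mean(axis=0)
        ras_auc = auc(X @ (mu1 - mu0), y)
        oracle_auc = auc(np.array(y, dtype=float), y)
        assert 0.7 <= ras_auc <= oracle_auc
        assert oracle_auc == 1.0

    def test_render_slide_composes_tissue_block(self):
        slide = render_slide("chondroid_low", np.random.default_rng(0), size=256,
                             tissue_margin=64)
        assert slide.shape == (256, 256, 3)
        assert np.allclose(slide[0, 0], 1.0)        # white corner
        assert slide[128, 128].mean() < 0.95        # tissue center


class TestPersistence:
    def test_write_cohort_latent_roundtrip(self, tmp_path):
        import pandas as pd

        cohort = generate_cohort(table1_spec(seed=4, n_patients=20))
        write_cohort(cohort, tmp_path, "latent")
        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == 20
        lat = pd.read_csv(tmp_path / "radiograph_latents.csv")
        assert len(lat) == 20

    def test_write_cohort_raster_writes_pngs(self, tmp_path):
        cohort = generate_cohort(table1_spec(seed=4, n_patients=10, render_mode="raster"))
        write_cohort(cohort, tmp_path, "raster")
        pngs = list((tmp_path / "radiographs").glob("*.png"))
        assert len(pngs) == 10
        paired = paired_subset(cohort)
        bag_dir = tmp_path / "histology" / paired[0].patient_id
        assert len(list(bag_dir.glob("*.png"))) == len(paired[0].histology_bag)
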