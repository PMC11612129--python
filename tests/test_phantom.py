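"""Generator invariants: determinism, descriptor frequencies, rendered pixel
statistics, the generative category table, and dataset/duplicate emission."""

import dataclasses
import json

import numpy as np
import pytest

from sonodescribe.errors import ConfigurationError, InputError
from sonodescribe.phantom import (
    PhantomSpec,
    classify_suggestivity,
    derive_birads,
    load_manifest,
    make_dataset,
    make_duplicates,
    manifest_checksum,
    render_phantom,
    sample_phantom_spec,
    split_folds,
)


def _neutral_spec(**overrides) -> PhantomSpec:
    base = dict(
        shape="oval", margin="circumscribed", orientation="parallel",
        echogenicity="hypoechoic", posterior="none", halo="absent",
        suggestivity="no_clear_suggestivity", malignant=False,
        center=(80.0, 48.0), semi_axes=(22.0, 14.0), rotation=0.0,
        background_mean=110.0, seed=7,
    )
    base.update(overrides)
    return PhantomSpec(**base)


class TestSampling:
    def test_same_seed_gives_identical_spec(self):
        assert sample_phantom_spec(7) == sample_phantom_spec(7)

    def test_round_shape_forces_no_orientation(self):
        weights = {"shape": {"oval": 0.0, "round": 1.0, "irregular": 0.0},
                   "suggestivity": {"simple_cyst": 0.0, "complex_cyst": 0.0,
                                    "fibroadenoma": 0.0,
                                    "no_clear_suggestivity": 1.0}}
        for seed in range(30):
            spec = sample_phantom_spec(seed, weights)
            assert spec.shape == "round"
            assert spec.orientation == "none"
            ratio = spec.semi_axes[0] / spec.semi_axes[1]
            assert 0.9 <= ratio <= 1.1

    def test_shape_frequencies_follow_weights(self):
        # Binomial bound: at n=2000, p=0.5 the sample frequency lies within
        # +-0.05 of p except with probability < 1e-5.
        weights = {"shape": {"oval": 0.5, "round": 0.25, "irregular": 0.25},
                   "suggestivity": {"simple_cyst": 0.0, "complex_cyst": 0.0,
                                    "fibroadenoma": 0.0,
                                    "no_clear_suggestivity": 1.0}}
        counts = {"oval": 0, "round": 0, "irregular": 0}
        n = 2000
        for seed in range(n):
            counts[sample_phantom_spec(seed, weights).shape] += 1
        assert abs(counts["oval"] / n - 0.5) < 0.05
        assert abs(counts["round"] / n - 0.25) < 0.05
        assert abs(counts["irregular"] / n - 0.25) < 0.05

    def test_suggestivity_roundtrips_from_descriptors(self):
        for seed in range(200):
            spec = sample_phantom_spec(seed)
            assert classify_suggestivity(spec.descriptors()) == spec.suggestivity

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_phantom_spec(0, {"shape": {"oval": -0.1, "round": 0.6,
                                              "irregular": 0.5}})
        with pytest.raises(ConfigurationError):
            sample_phantom_spec(0, {"shape": {"oval": 0.5, "round": 0.2,
                                              "irregular": 0.2}})

    def test_spec_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            _neutral_spec(shape="round", orientation="parallel")
        with pytest.raises(ConfigurationError):
            _neutral_spec(margin="spiculated", malignant=False)
        with pytest.raises(ConfigurationError):
            _neutral_spec(suggestivity="simple_cyst")


class TestRendering:
    def test_rendering_is_deterministic(self):
        spec = sample_phantom_spec(13)
        img1, box1 = render_phantom(spec)
        img2, box2 = render_phantom(spec)
        assert np.array_equal(img1, img2)
        assert box1 == box2

    def _interior_mean(self, spec, img):
        h, w = img.shape
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = spec.center
        rx, ry = spec.semi_axes
        rho = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
        return float(img[rho < 0.6].mean())

    def test_anechoic_interior_darker_than_half_background(self):
        spec = _neutral_spec(echogenicity="anechoic")
        img, _ = render_phantom(spec)
        assert self._interior_mean(spec, img) < 0.5 * spec.background_mean

    def test_echogenicity_intensity_ordering(self):
        means = {}
        for echo in ("anechoic", "hypoechoic", "isoechoic", "hyperechoic"):
            spec = _neutral_spec(echogenicity=echo)
            means[echo] = self._interior_mean(spec, render_phantom(spec)[0])
        assert (means["anechoic"] < means["hypoechoic"]
                < means["isoechoic"] < means["hyperechoic"])
        # isoechoic tracks the background level
        assert abs(means["isoechoic"] - 110.0) < 15.0

    @pytest.mark.parametrize("posterior,brighter", [("enhancement", True),
                                                    ("shadowing", False)])
    def test_posterior_column_statistic(self, posterior, brighter):
        spec = _neutral_spec(echogenicity="anechoic", posterior=posterior)
        img, _ = render_phantom(spec)
        cx, cy = spec.center
        rx, ry = spec.semi_axes
        y0, y1 = int(cy + 1.3 * ry), int(cy + 3.0 * ry)
        column = img[y0:y1, int(cx - 0.6 * rx):int(cx + 0.6 * rx)].mean()
        flank = img[y0:y1, 5:15].mean()
        assert (column > flank) == brighter

    def test_box_encloses_nodule_and_posterior_column(self):
        spec = _neutral_spec(posterior="enhancement")
        _, box = render_phantom(spec)
        cx, cy = spec.center
        rx, ry = spec.semi_axes
        assert box.x0 <= cx - rx and box.x1 >= cx + rx
        assert box.y0 <= cy - ry
        assert box.y1 >= cy + ry + 1.5 * ry  # posterior column included

    def test_nodule_outside_canvas_rejected(self):
        from sonodescribe.errors import GeometryError
        with pytest.raises(GeometryError):
            render_phantom(_neutral_spec(center=(5.0, 48.0)))


class TestGenerativeTable:
    def test_simple_cyst_maps_to_2(self):
        spec = _neutral_spec(echogenicity="anechoic", posterior="enhancement",
                             suggestivity="simple_cyst")
        assert derive_birads(spec) == "2"

    def test_spiculated_maps_to_5(self):
        spec = _neutral_spec(margin="spiculated", malignant=True)
        assert derive_birads(spec) == "5"

    def test_benign_oval_pattern_maps_to_3(self):
        assert derive_birads(_neutral_spec()) == "3"

    def test_monotone_in_suspicious_feature_count(self):
        d = _neutral_spec().descriptors()
        assert derive_birads(d) == "3"
        d["shape"] = "irregular"
        assert derive_birads(d) == "4A"
        d["posterior"] = "shadowing"
        assert derive_birads(d) == "4B"
        d["halo"] = "present"
        assert derive_birads(d) == "4C"
        d["orientation"] = "anti_parallel"
        assert derive_birads(d) == "5"

    def test_total_over_sampled_specs(self):
        for seed in range(300):
            spec = sample_phantom_spec(seed)
            cat = derive_birads(spec)
            assert cat in ("2", "3", "4A", "4B", "4C", "5")
            if spec.suggestivity == "simple_cyst":
                assert cat == "2"
            if spec.margin == "spiculated":
                assert cat == "5"


class TestDatasetEmission:
    def test_counts_and_files(self, small_manifest, tmp_path):
        root = small_manifest["root"]
        from pathlib import Path
        assert len(list(Path(root, "images").glob("img_*.png"))) == 12
        assert len(list(Path(root, "boxes").glob("img_*.txt"))) == 12
        import pandas as pd
        labels = pd.read_csv(Path(root, "labels.csv"))
        assert len(labels) == 12

    def test_same_seed_same_manifest_checksum(self, tmp_path):
        m1 = make_dataset(5, seed=3, out_dir=tmp_path / "a")
        m2 = make_dataset(5, seed=3, out_dir=tmp_path / "b")
        m1["root"] = m2["root"] = ""
        assert manifest_checksum(m1) == manifest_checksum(m2)

    def test_manifest_roundtrips_from_disk(self, small_manifest):
        from pathlib import Path
        loaded = load_manifest(Path(small_manifest["root"]) / "manifest.json")
        assert loaded["n"] == small_manifest["n"]
        assert [r["image_id"] for r in loaded["records"]] == \
               [r["image_id"] for r in small_manifest["records"]]

    def test_extra_info_never_in_validation_folds(self, tmp_path):
        manifest = make_dataset(30, seed=8, out_dir=tmp_path,
                                extra_info_fraction=0.3)
        flagged = {r["image_id"] for r in manifest["records"] if r["extra_info"]}
        assert flagged  # fixture should flag something at 30%
        folds = split_folds(manifest, k=10, seed=0)
        for fold in folds:
            assert not flagged & set(fold["val"])
            assert flagged <= set(fold["train"])

    def test_box_file_roundtrip(self, small_manifest):
        from pathlib import Path
        from sonodescribe.phantom import read_box_file
        from sonodescribe.roi_types import BoundingBox
        rec = small_manifest["records"][0]
        canvas = tuple(small_manifest["canvas"])
        box = read_box_file(Path(small_manifest["root"]) / rec["box_file"], canvas)
        truth = BoundingBox(*rec["box"])
        assert abs(box.x0 - truth.x0) <= 1 and abs(box.y1 - truth.y1) <= 1

    def test_n_zero_rejected(self, tmp_path):
        with pytest.raises(InputError):
            make_dataset(0, seed=0, out_dir=tmp_path)


class TestDuplicates:
    def test_planted_counts_and_provenance(self, dup_manifest):
        dups = [r for r in dup_manifest["records"] if r["duplicate_of"]]
        assert len(dups) == 5
        # conflict fraction 0.4 of 5 pairs -> floor(2.0) = 2 flipped labels
        conflicted = [r for r in dups if r["duplicate_of"]["label_conflict"]]
        assert len(conflicted) == 2
        sources = {r["image_id"] for r in dup_manifest["records"]
                   if not r["duplicate_of"]}
        for rec in dups:
            assert rec["duplicate_of"]["image_id"] in sources
            assert abs(rec["duplicate_of"]["rotation_deg"]) <= 15.0
            assert 0.8 <= rec["duplicate_of"]["zoom"] <= 1.2

    def test_conflicted_copies_flip_malignancy(self, dup_manifest):
        by_id = {r["image_id"]: r for r in dup_manifest["records"]}
        for rec in dup_manifest["records"]:
            if rec["duplicate_of"]:
                src = by_id[rec["duplicate_of"]["image_id"]]
                if rec["duplicate_of"]["label_conflict"]:
                    assert rec["malignant"] != src["malignant"]
                else:
                    assert rec["malignant"] == src["malignant"]

    def test_empty_manifest_rejected(self):
        with pytest.raises(InputError):
            make_duplicates({"records": [], "root": ".", "canvas": [160, 160]},
                            n_pairs=1)
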