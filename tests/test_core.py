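"""Container construction, validation, accessors, subsetting and combining."""

import numpy as np
import pandas as pd
import pytest

import spotframe as sf
from spotframe.errors import (
    DimensionMismatch,
    DuplicateKey,
    FeatureMismatch,
    OrphanImage,
    SampleClash,
    SelectorOutOfRange,
    UnknownComponent,
    UnknownEntry,
    UnknownID,
    ValidationError,
)

from conftest import random_dataset


class TestConstruction:
    def test_defaults_from_bare_matrix(self):
        ds = sf.SpatialDataset(np.zeros((3, 4)))
        assert ds.shape == (3, 4)
        assert ds.assay_names == ("counts",)
        assert list(ds.col_annotations["sample_id"]) == ["sample01"] * 4
        assert len(set(ds.feature_ids)) == 3
        assert ds.spatial_coords.shape == (4, 0)

    def test_col_annotation_length_mismatch_names_component(self):
        cols = pd.DataFrame({"barcode_id": [f"b{i}" for i in range(5)]})
        with pytest.raises(DimensionMismatch, match="col_annotations"):
            sf.SpatialDataset(np.zeros((3, 4)), col_annotations=cols)

    def test_axis_names_preserved_verbatim(self):
        ds = sf.SpatialDataset(
            np.zeros((3, 4)), spatial_coords=np.zeros((4, 2)), spatial_coords_names=("x", "y")
        )
        assert ds.spatial_coords_names == ("x", "y")

    def test_default_axis_names_are_visium_pixel_names(self):
        ds = sf.SpatialDataset(np.zeros((3, 4)), spatial_coords=np.ones((4, 2)))
        assert ds.spatial_coords_names == ("pxl_col_in_fullres", "pxl_row_in_fullres")

    def test_duplicate_feature_id_rejected(self):
        rows = pd.DataFrame({"feature_id": ["a", "a", "b"]})
        with pytest.raises(DuplicateKey):
            sf.SpatialDataset(np.zeros((3, 4)), row_annotations=rows)

    def test_duplicate_obs_key_rejected_but_barcode_reuse_across_samples_ok(self):
        cols = pd.DataFrame({"barcode_id": ["b", "b"], "sample_id": ["s1", "s2"]})
        ds = sf.SpatialDataset(np.zeros((2, 2)), col_annotations=cols)
        assert ds.n_obs == 2
        cols2 = pd.DataFrame({"barcode_id": ["b", "b"], "sample_id": ["s1", "s1"]})
        with pytest.raises(DuplicateKey):
            sf.SpatialDataset(np.zeros((2, 2)), col_annotations=cols2)

    def test_nan_coords_must_be_flagged(self):
        coords = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(DimensionMismatch, match="flagged"):
            sf.SpatialDataset(
                np.zeros((2, 2)), spatial_coords=coords, coords_valid=[True, True]
            )
        ds = sf.SpatialDataset(np.zeros((2, 2)), spatial_coords=coords)
        assert list(ds.coords_valid) == [True, False]

    def test_failures_are_collected_not_one_at_a_time(self):
        rows = pd.DataFrame({"feature_id": ["a", "a", "b"]})
        cols = pd.DataFrame({"barcode_id": [f"b{i}" for i in range(5)]})
        with pytest.raises(ValidationError) as err:
            sf.SpatialDataset(np.zeros((3, 4)), row_annotations=rows, col_annotations=cols)
        assert len(err.value.findings) >= 2
        classes = {cls for cls, _ in err.value.findings}
        assert DuplicateKey in classes and DimensionMismatch in classes

    def test_orphan_image_rejected(self):
        table = sf.ImageTable([sf.ImageRow("ghost", "lowres", 0.1, sf.SpatialImage(source="x.png"))])
        with pytest.raises(OrphanImage):
            sf.SpatialDataset(np.zeros((2, 2)), image_table=table)


class TestAccessors:
    def test_get_component_dispatch(self, small_dataset):
        ds = small_dataset
        assert ds.get_component("assay", "counts").shape == ds.shape
        assert ds.get_component("spatial_coords_names") == ds.spatial_coords_names
        assert ds.get_component("sample_ids") == ("s1",)
        with pytest.raises(UnknownEntry):
            ds.get_component("assay", "logcounts")
        with pytest.raises(UnknownComponent):
            ds.get_component("frobnicate")

    def test_sample_ids_deduplicated_first_appearance_order(self, rng):
        ds = random_dataset(rng, n_obs=6, n_samples=3)
        assert ds.sample_ids == ("s1", "s2", "s3")

    def test_set_assay_appends_in_insertion_order(self, small_dataset):
        ds2 = small_dataset.set_component("assay", np.ones(small_dataset.shape), "logcounts")
        assert ds2.assay_names == ("counts", "logcounts")
        assert small_dataset.assay_names == ("counts",)  # original untouched

    def test_set_component_revalidates(self, small_dataset):
        with pytest.raises(DimensionMismatch):
            small_dataset.set_component("spatial_coords", np.zeros((2, 2)))

    def test_coord_names_round_trip(self, small_dataset):
        ds2 = small_dataset.set_component("spatial_coords_names", ("x", "y"))
        assert ds2.get_component("spatial_coords_names") == ("x", "y")


class TestSubset:
    def test_boolean_mask_and_id_list(self, rng):
        ds = random_dataset(rng, n_features=6, n_obs=8, with_visium_cols=True)
        mask = ds.col_annotations["in_tissue"].to_numpy()
        sub = ds.subset(obs=mask)
        assert sub.n_obs == int(mask.sum())
        assert sub.spatial_coords.shape[0] == sub.n_obs
        byid = ds.subset(features=["g2", "g0"])
        assert byid.feature_ids == ["g2", "g0"]  # selector order preserved

    def test_selector_errors(self, small_dataset):
        with pytest.raises(SelectorOutOfRange):
            small_dataset.subset(obs=[99])
        with pytest.raises(UnknownID):
            small_dataset.subset(features=["nope"])

    def test_feature_subset_keeps_reduced_dims(self, rng):
        ds = random_dataset(rng)
        sub = ds.subset(features=[0, 1])
        assert sub.reduced_dim("pca").shape == (ds.n_obs, 3)

    def test_image_rows_of_vanished_samples_are_dropped(self, rng):
        ds = random_dataset(rng, n_obs=6, n_samples=2)
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        ds = sf.add_image(ds, "s1", "lowres", px, 0.5)
        ds = sf.add_image(ds, "s2", "lowres", px, 0.5)
        keep = (ds.col_annotations["sample_id"] == "s1").to_numpy()
        sub = ds.subset(obs=keep)
        assert [r.sample_id for r in sub.image_table] == ["s1"]

    def test_composition_matches_single_combined_subset(self, rng):
        """subset(subset(ds, F1, O1), F2, O2) == subset(ds, F1[F2], O1[O2])."""
        for _ in range(10):
            ds = random_dataset(rng, n_features=5, n_obs=6, n_samples=2, with_visium_cols=True)
            f1 = np.sort(rng.choice(5, size=4, replace=False))
            o1 = np.sort(rng.choice(6, size=5, replace=False))
            f2 = np.sort(rng.choice(len(f1), size=3, replace=False))
            o2 = np.sort(rng.choice(len(o1), size=3, replace=False))
            two_step = ds.subset(features=f1, obs=o1).subset(features=f2, obs=o2)
            one_step = ds.subset(features=f1[f2], obs=o1[o2])
            assert sf.dataset_differences(two_step, one_step) == []


class TestCombine:
    def test_concatenation_shapes_and_sample_ids(self, rng):
        a = random_dataset(rng, n_features=10, n_obs=4)
        b = random_dataset(rng, n_features=10, n_obs=6)
        b = sf.SpatialDataset(
            {"counts": b.assay("counts")},
            row_annotations=a.row_annotations,
            col_annotations=b.col_annotations.assign(sample_id="other"),
            spatial_coords=b.spatial_coords,
            reduced_dims={"pca": b.reduced_dim("pca")},
        )
        both = sf.combine([a, b])
        assert both.shape == (10, 10)
        assert both.sample_ids == ("s1", "other")

    def test_feature_mismatch_raises(self, rng):
        a = random_dataset(rng, n_features=4)
        b = random_dataset(rng, n_features=5)
        with pytest.raises(FeatureMismatch):
            sf.combine([a, b])

    def test_sample_clash_and_suffixing(self, rng):
        a = random_dataset(rng)
        b = random_dataset(rng)
        with pytest.raises(SampleClash):
            sf.combine([a, b], sample_id_policy="require_unique")
        both = sf.combine([a, b], sample_id_policy="suffix_on_clash")
        assert both.sample_ids == ("s1", "s1.1")

    def test_combine_then_subset_recovers_inputs(self, rng):
        """Per-sample subsetting of a combined dataset gives back each input
        component-wise (up to the sample_id suffix)."""
        for _ in range(5):
            parts = [random_dataset(rng, n_obs=4 + k) for k in range(3)]
            parts = [
                p if i == 0 else sf.SpatialDataset(
                    {"counts": p.assay("counts")},
                    row_annotations=parts[0].row_annotations,
                    col_annotations=p.col_annotations,
                    spatial_coords=p.spatial_coords,
                    reduced_dims={"pca": p.reduced_dim("pca")},
                )
                for i, p in enumerate(parts)
            ]
            both = sf.combine(parts, sample_id_policy="suffix_on_clash")
            for i, (part, sid) in enumerate(zip(parts, both.sample_ids)):
                back = both.subset(obs=(both.col_annotations["sample_id"] == sid).to_numpy())
                renamed = part.col_annotations.assign(sample_id=sid)
                expect = sf.SpatialDataset(
                    {"counts": part.assay("counts")},
                    row_annotations=part.row_annotations,
                    col_annotations=renamed,
                    spatial_coords=part.spatial_coords,
                    reduced_dims={"pca": part.reduced_dim("pca")},
                )
                assert sf.dataset_differences(back, expect) == []
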