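"""Space Ranger bundle reading, writing, dialects and validation."""

import gzip
import os
import shutil

import numpy as np
import pytest

import spotframe as sf
from spotframe.errors import BarcodeJoinError, DialectError, MissingFile, NotVisiumShaped
from spotframe.visium import POSITIONS_V1, POSITIONS_V2


def mtx_value_sum(path):
    """Independent line-by-line scan of a Matrix Market triplet file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    total = 0
    with opener(path, "rt") as fh:
        header_seen = False
        for line in fh:
            if line.startswith("%"):
                continue
            if not header_seen:
                header_seen = True  # dims line
                continue
            total += float(line.split()[2])
    return total


class TestDialectDetection:
    def test_both_dialects_and_column_count(self, tmp_path):
        v2 = tmp_path / "p2.csv"
        v2.write_text("barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres\n")
        assert sf.detect_positions_dialect(v2) == "v2_header"
        v1 = tmp_path / "p1.csv"
        v1.write_text("AAACAACGAATAGTTC-1,1,0,0,100,200\n")
        assert sf.detect_positions_dialect(v1) == "v1_headerless"
        bad = tmp_path / "p5.csv"
        bad.write_text("a,b,c,d,e\n")
        with pytest.raises(DialectError):
            sf.detect_positions_dialect(bad)


class TestReader:
    def test_reader_matches_manifest(self, visium_bundle):
        root, manifest = visium_bundle
        ds = sf.read_visium(root)
        assert ds.shape == (manifest.n_genes, manifest.n_spots)
        assert int(ds.col_annotations["in_tissue"].sum()) == manifest.n_in_tissue
        assert ds.assay_names == ("counts",)
        assert int(ds.assay("counts").sum()) == manifest.total_counts
        assert ds.spatial_coords_names == ("pxl_col_in_fullres", "pxl_row_in_fullres")
        truth = {s["barcode"]: s for s in manifest.spots}
        for i, bc in enumerate(ds.col_annotations["barcode_id"]):
            assert ds.spatial_coords[i, 0] == truth[bc]["pxl_col_in_fullres"]
            assert ds.spatial_coords[i, 1] == truth[bc]["pxl_row_in_fullres"]

    def test_counts_sum_matches_independent_mtx_scan(self, visium_bundle):
        root, _ = visium_bundle
        ds = sf.read_visium(root)
        path = os.path.join(root, "filtered_feature_bc_matrix", "matrix.mtx")
        assert float(ds.assay("counts").sum()) == mtx_value_sum(path)

    def test_dialect_equivalence(self, visium_bundle, tmp_path):
        """v1-only and v2-only copies of the same bundle read identically."""
        root, _ = visium_bundle
        for keep, drop, name in ((POSITIONS_V2, POSITIONS_V1, "v2"), (POSITIONS_V1, POSITIONS_V2, "v1")):
            dst = tmp_path / name
            shutil.copytree(root, dst)
            (dst / "spatial" / drop).unlink()
        ds_v1 = sf.read_visium(tmp_path / "v1")
        ds_v2 = sf.read_visium(tmp_path / "v2")
        assert sf.dataset_differences(ds_v1, ds_v2) == []

    def test_lazy_image_mode_stored(self, visium_bundle):
        root, _ = visium_bundle
        ds = sf.read_visium(root, image_ids=("lowres",), load_images=False)
        row = sf.get_image(ds, "sample01", "lowres")[0]
        assert row.image.mode == "stored"
        assert row.image.pixels is None

    def test_missing_positions_barcodes_are_flagged(self, visium_bundle, tmp_path):
        root, manifest = visium_bundle
        dst = tmp_path / "mut"
        shutil.copytree(root, dst)
        # drop the first 3 position rows -> those barcodes get flagged-missing
        pos = dst / "spatial" / POSITIONS_V2
        lines = pos.read_text().splitlines()
        pos.write_text("\n".join([lines[0]] + lines[4:]) + "\n")
        (dst / "spatial" / POSITIONS_V1).unlink()
        ds = sf.read_visium(dst)
        dropped = {line.split(",")[0] for line in lines[1:4]}
        mask = ds.col_annotations["barcode_id"].isin(dropped).to_numpy()
        assert (~ds.coords_valid[mask]).all()
        assert np.isnan(ds.spatial_coords[mask]).all()
        assert (ds.col_annotations.loc[mask, "array_row"] == -1).all()
        assert ds.coords_valid[~mask].all()

    def test_total_barcode_mismatch_raises(self, visium_bundle, tmp_path):
        root, _ = visium_bundle
        dst = tmp_path / "mut"
        shutil.copytree(root, dst)
        pos = dst / "spatial" / POSITIONS_V2
        lines = pos.read_text().splitlines()
        renamed = [lines[0]] + ["XX" + line for line in lines[1:]]
        pos.write_text("\n".join(renamed) + "\n")
        (dst / "spatial" / POSITIONS_V1).unlink()
        with pytest.raises(BarcodeJoinError):
            sf.read_visium(dst)

    def test_missing_file_names_the_file(self, tmp_path):
        with pytest.raises(MissingFile, match="matrix directory"):
            sf.read_visium(tmp_path / "nope")

    def test_gzipped_triplet_reads_identically(self, visium_bundle, tmp_path):
        root, _ = visium_bundle
        dst = tmp_path / "gz"
        shutil.copytree(root, dst)
        mdir = dst / "filtered_feature_bc_matrix"
        for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
            with open(mdir / name, "rb") as fin, gzip.open(str(mdir / name) + ".gz", "wb") as fout:
                fout.write(fin.read())
            (mdir / name).unlink()
        assert sf.dataset_differences(sf.read_visium(dst), sf.read_visium(root)) == []

    def test_two_directories_combine_with_unique_samples(self, visium_bundle, tmp_path):
        root, manifest = visium_bundle
        other = tmp_path / "other"
        m2 = sf.make_visium_fixture(other, n_array_rows=4, n_array_cols=4, n_genes=60, seed=12)
        ds = sf.read_visium([root, other], sample_ids=["a", "b"])
        assert ds.sample_ids == ("a", "b")
        assert ds.n_obs == manifest.n_spots + m2.n_spots


class TestWriter:
    def test_round_trip_identity(self, visium_bundle, tmp_path):
        root, _ = visium_bundle
        first = sf.read_visium(root)
        sf.write_bundle(first, tmp_path / "out")
        second = sf.read_visium(tmp_path / "out")
        assert sf.dataset_differences(first, second) == []

    def test_written_bundle_validates_clean(self, visium_bundle, tmp_path):
        root, _ = visium_bundle
        sf.write_bundle(sf.read_visium(root), tmp_path / "out")
        assert sf.validate_bundle(tmp_path / "out") == []

    def test_not_visium_shaped(self, rng, tmp_path):
        from conftest import random_dataset

        ds = random_dataset(rng)  # lacks in_tissue/array_* columns
        with pytest.raises(NotVisiumShaped, match="in_tissue"):
            sf.write_bundle(ds, tmp_path / "out")


class TestValidator:
    def test_pristine_bundle_has_zero_findings(self, visium_bundle):
        root, _ = visium_bundle
        assert sf.validate_bundle(root) == []

    def test_deleted_scalefactors_is_one_missing_file(self, visium_bundle, tmp_path):
        root, _ = visium_bundle
        dst = tmp_path / "mut"
        shutil.copytree(root, dst)
        (dst / "spatial" / "scalefactors_json.json").unlink()
        findings = sf.validate_bundle(dst)
        assert [f["code"] for f in findings] == ["MissingFile"]
        assert "scalefactors" in findings[0]["message"]

    def test_renamed_positions_barcodes_counted(self, visium_bundle, tmp_path):
        root, _ = visium_bundle
        dst = tmp_path / "mut"
        shutil.copytree(root, dst)
        for name in (POSITIONS_V2, POSITIONS_V1):
            pos = dst / "spatial" / name
            lines = pos.read_text().splitlines()
            head = 1 if name == POSITIONS_V2 else 0
            for k in range(head, head + 3):
                lines[k] = "ZZ" + lines[k]
            pos.write_text("\n".join(lines) + "\n")
        findings = sf.validate_bundle(dst)
        mismatches = [f for f in findings if f["code"] == "BarcodeMismatch"]
        assert sorted(f["n_unmatched"] for f in mismatches) == [3, 3]

    def test_out_of_range_scale_factor(self, visium_bundle, tmp_path):
        import json

        root, _ = visium_bundle
        dst = tmp_path / "mut"
        shutil.copytree(root, dst)
        sfpath = dst / "spatial" / "scalefactors_json.json"
        d = json.loads(sfpath.read_text())
        d["tissue_lowres_scalef"] = 3.0
        sfpath.write_text(json.dumps(d))
        findings = sf.validate_bundle(dst)
        assert any(f["code"] == "ScaleFactorError" for f in findings)
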