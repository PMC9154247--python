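"""Reading and writing 10x Visium Space Ranger output directories.

A Space Ranger bundle looks like::

    <root>/
      filtered_feature_bc_matrix/   (or raw_feature_bc_matrix/)
        matrix.mtx[.gz]             Matrix Market triplet, features x barcodes
        barcodes.tsv[.gz]           one barcode per line
        features.tsv[.gz]           feature_id <TAB> symbol [<TAB> type]
      spatial/
        tissue_positions.csv        v2: with header line, OR
        tissue_positions_list.csv   v1: headerless, same six columns
        scalefactors_json.json
        tissue_lowres_image.png     (and/or tissue_hires_image.png)

The positions file changed between Space Ranger versions: v1 is headerless,
v2 starts with a ``barcode,...`` header.  Both carry the same six columns
(barcode, in_tissue, array_row, array_col, pxl_row_in_fullres,
pxl_col_in_fullres).  The dialect is detected from content, never from the
file name.  Note the source stores (row, col) pixel order while the
dataset's coordinate axes are (col, row) — axis 0 of ``spatial_coords`` is
horizontal — so spot coordinates overlay images without transposition.

Barcodes present in the matrix but absent from the positions file (possible
with the raw matrix) get flagged-missing coordinates, ``in_tissue=False``
and lattice indices of -1; positions rows absent from the matrix are ignored
with a logged count.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import core
from .errors import BarcodeJoinError, DialectError, MissingFile, NotVisiumShaped
from .images import ImageRow, ImageTable, SpatialImage

logger = logging.getLogger(__name__)

MATRIX_DIRS = {"raw": "raw_feature_bc_matrix", "filtered": "filtered_feature_bc_matrix"}
POSITIONS_V2 = "tissue_positions.csv"
POSITIONS_V1 = "tissue_positions_list.csv"
SCALEFACTORS = "scalefactors_json.json"
IMAGE_FILES = {"lowres": "tissue_lowres_image.png", "hires": "tissue_hires_image.png"}
SCALEF_KEYS = {"lowres": "tissue_lowres_scalef", "hires": "tissue_hires_scalef"}
POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


@dataclass
class VisiumBundle:
    """Descriptor of one Space Ranger-layout directory."""

    root: str
    matrix_dir: str
    positions_file: str
    dialect: str
    scalefactors_file: str
    image_files: dict = field(default_factory=dict)


def _maybe_gz(path):
    """Return the path, its .gz sibling, or None — gzip is suffix-detected."""
    if os.path.exists(path):
        return path
    if os.path.exists(path + ".gz"):
        return path + ".gz"
    return None


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def locate_bundle(root, data_choice="filtered") -> VisiumBundle:
    """Resolve a bundle's files, raising MissingFile naming what is absent."""
    if data_choice not in MATRIX_DIRS:
        raise ValueError(f"data_choice must be raw|filtered, got {data_choice!r}")
    mdir = os.path.join(root, MATRIX_DIRS[data_choice])
    if not os.path.isdir(mdir):
        raise MissingFile(f"matrix directory not found: {mdir}")
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if _maybe_gz(os.path.join(mdir, name)) is None:
            raise MissingFile(f"missing {name}(.gz) in {mdir}")
    spatial = os.path.join(root, "spatial")
    positions = None
    for name in (POSITIONS_V2, POSITIONS_V1):  # prefer the v2 file when both exist
        cand = os.path.join(spatial, name)
        if os.path.exists(cand):
            positions = cand
            break
    if positions is None:
        raise MissingFile(f"missing {POSITIONS_V2} / {POSITIONS_V1} in {spatial}")
    dialect = detect_positions_dialect(positions)
    scalef = os.path.join(spatial, SCALEFACTORS)
    if not os.path.exists(scalef):
        raise MissingFile(f"missing {SCALEFACTORS} in {spatial}")
    images = {
        img_id: path
        for img_id, name in IMAGE_FILES.items()
        if os.path.exists(path := os.path.join(spatial, name))
    }
    return VisiumBundle(str(root), mdir, positions, dialect, scalef, images)


def detect_positions_dialect(path) -> str:
    """``v2_header`` iff the first cell is the literal ``barcode``.

    Either way the file must have six columns; anything else is a
    DialectError.
    """
    with _open_text(path) as fh:
        first = fh.readline().strip()
    if not first:
        raise DialectError(f"{path}: empty positions file")
    cells = first.split(",")
    if len(cells) != len(POSITION_COLUMNS):
        raise DialectError(
            f"{path}: expected {len(POSITION_COLUMNS)} columns, found {len(cells)}"
        )
    return "v2_header" if cells[0] == "barcode" else "v1_headerless"


def _read_positions(path, dialect) -> pd.DataFrame:
    if dialect == "v2_header":
        df = pd.read_csv(path, header=0)
        if list(df.columns) != POSITION_COLUMNS:
            raise DialectError(
                f"{path}: header {list(df.columns)} != expected {POSITION_COLUMNS}"
            )
    else:
        df = pd.read_csv(path, header=None, names=POSITION_COLUMNS)
    return df


def _read_matrix_triplet(mdir):
    mtx = _maybe_gz(os.path.join(mdir, "matrix.mtx"))
    with (gzip.open(mtx, "rb") if mtx.endswith(".gz") else open(mtx, "rb")) as fh:
        counts = scipy.io.mmread(fh)
    counts = sp.csr_matrix(counts)
    if np.all(counts.data == np.round(counts.data)):
        counts = counts.astype(np.int64)
    with _open_text(_maybe_gz(os.path.join(mdir, "barcodes.tsv"))) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    with _open_text(_maybe_gz(os.path.join(mdir, "features.tsv"))) as fh:
        feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    rows = {"feature_id": [f[0] for f in feats]}
    if all(len(f) >= 2 for f in feats):
        rows["symbol"] = [f[1] for f in feats]
    if all(len(f) >= 3 for f in feats):
        rows["feature_type"] = [f[2] for f in feats]
    row_annotations = pd.DataFrame(rows)
    if counts.shape != (len(row_annotations), len(barcodes)):
        raise DialectError(
            f"matrix shape {counts.shape} does not match {len(row_annotations)} "
            f"features x {len(barcodes)} barcodes"
        )
    return counts, row_annotations, barcodes


def read_visium(
    dirs,
    sample_ids=None,
    data_choice="filtered",
    image_ids=("lowres",),
    load_images=False,
):
    """Build a :class:`~spotframe.core.SpatialDataset` from Space Ranger output.

    Parameters
    ----------
    dirs
        One bundle directory, or a sequence of them (one per sample;
        combined with unique sample ids required).
    sample_ids
        Sample id per directory; defaults to ``sample01``, ``sample02``, ...
    data_choice
        ``"filtered"`` (default, tissue-associated barcodes only) or
        ``"raw"`` (all barcodes).
    image_ids
        Which downsampled images to register (subset of lowres/hires).
    load_images
        Realize images into memory now; otherwise rows stay mode "stored".
    """
    if isinstance(dirs, (str, os.PathLike)):
        dirs = [dirs]
    dirs = [str(d) for d in dirs]
    if sample_ids is None:
        sample_ids = [f"sample{i + 1:02d}" for i in range(len(dirs))]
    if len(sample_ids) != len(dirs):
        raise ValueError(f"{len(dirs)} directories but {len(sample_ids)} sample_ids")
    parts = [
        _read_one(d, s, data_choice, tuple(image_ids), load_images)
        for d, s in zip(dirs, sample_ids)
    ]
    if len(parts) == 1:
        return parts[0]
    return core.combine(parts, sample_id_policy="require_unique")


def _read_one(root, sample_id, data_choice, image_ids, load_images):
    bundle = locate_bundle(root, data_choice)
    counts, row_annotations, barcodes = _read_matrix_triplet(bundle.matrix_dir)
    positions = _read_positions(bundle.positions_file, bundle.dialect)

    pos = positions.set_index("barcode")
    if pos.index.duplicated().any():
        raise DialectError(f"{bundle.positions_file}: duplicated barcodes")
    matched = [b for b in barcodes if b in pos.index]
    if len(positions) and not matched:
        raise BarcodeJoinError(
            f"{root}: no barcode shared between matrix ({len(barcodes)}) and "
            f"positions ({len(positions)}) — wrong directory pairing?"
        )
    ignored = len(pos.index.difference(pd.Index(barcodes)))
    if ignored:
        logger.info("%s: %d positions row(s) without a matrix barcode ignored", root, ignored)

    n_obs = len(barcodes)
    in_tissue = np.zeros(n_obs, dtype=bool)
    array_row = np.full(n_obs, -1, dtype=np.int64)
    array_col = np.full(n_obs, -1, dtype=np.int64)
    coords = np.full((n_obs, 2), np.nan)
    valid = np.zeros(n_obs, dtype=bool)
    hit = pd.Index(barcodes).isin(pos.index)
    if hit.any():
        sub = pos.loc[np.asarray(barcodes)[hit]]
        in_tissue[hit] = sub["in_tissue"].to_numpy() != 0
        array_row[hit] = sub["array_row"].to_numpy()
        array_col[hit] = sub["array_col"].to_numpy()
        coords[hit, 0] = sub["pxl_col_in_fullres"].to_numpy(dtype=float)
        coords[hit, 1] = sub["pxl_row_in_fullres"].to_numpy(dtype=float)
        valid[hit] = True

    col_annotations = pd.DataFrame(
        {
            "barcode_id": barcodes,
            "sample_id": sample_id,
            "in_tissue": in_tissue,
            "array_row": array_row,
            "array_col": array_col,
        }
    )

    with open(bundle.scalefactors_file) as fh:
        scalefactors = json.load(fh)

    image_rows = []
    for img_id in image_ids:
        if img_id not in IMAGE_FILES:
            raise ValueError(f"unknown image id {img_id!r}; use lowres/hires")
        path = bundle.image_files.get(img_id)
        if path is None:
            raise MissingFile(f"requested image {img_id!r} but {IMAGE_FILES[img_id]} absent in {root}")
        key = SCALEF_KEYS[img_id]
        if key not in scalefactors:
            raise MissingFile(f"{bundle.scalefactors_file} lacks key {key!r}")
        img = SpatialImage(source=path)
        if load_images:
            img = img.realize()
        image_rows.append(ImageRow(sample_id, img_id, float(scalefactors[key]), img))

    return core.SpatialDataset(
        {"counts": counts},
        row_annotations=row_annotations,
        col_annotations=col_annotations,
        spatial_coords=coords,
        spatial_coords_names=core.DEFAULT_COORD_NAMES,
        coords_valid=valid,
        image_table=ImageTable(image_rows),
        metadata={"scalefactors": {sample_id: scalefactors}},
    )


# ---------------------------------------------------------------------- #
# writer


def _fmt_pixel(v):
    """Integer pixels stay integers in the CSV so round-trips are bit-exact."""
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_bundle(dataset, root, sample_id=None) -> VisiumBundle:
    """Write one sample of a Visium-shaped dataset as a Space Ranger bundle.

    Emits the filtered matrix triplet, a v2-header positions CSV (rows for
    observations with valid coordinates only), the scale-factor JSON and any
    loaded/stored images as PNG.  ``read_visium(write_bundle(ds))``
    reproduces ``ds`` component-wise.
    """
    sids = dataset.sample_ids
    if sample_id is None:
        if len(sids) != 1:
            raise NotVisiumShaped(f"multi-sample dataset; pass sample_id (have {sids})")
        sample_id = sids[0]
    if sample_id not in sids:
        raise NotVisiumShaped(f"sample_id {sample_id!r} not in dataset (have {sids})")
    ds = dataset.subset(obs=(dataset.col_annotations["sample_id"] == sample_id).to_numpy())

    problems = []
    if "counts" not in ds.assay_names:
        problems.append("no 'counts' assay")
    for col in ("in_tissue", "array_row", "array_col"):
        if col not in ds.col_annotations.columns:
            problems.append(f"col_annotations lacks {col!r}")
    if ds.spatial_coords.shape[1] != 2:
        problems.append(f"need 2 coordinate axes, have {ds.spatial_coords.shape[1]}")
    if problems:
        raise NotVisiumShaped("; ".join(problems))

    root = str(root)
    mdir = os.path.join(root, MATRIX_DIRS["filtered"])
    spatial = os.path.join(root, "spatial")
    os.makedirs(mdir, exist_ok=True)
    os.makedirs(spatial, exist_ok=True)

    counts = ds.assay("counts")
    coo = sp.coo_matrix(counts)
    integer = np.issubdtype(coo.dtype, np.integer) or np.all(coo.data == np.round(coo.data))
    scipy.io.mmwrite(
        os.path.join(mdir, "matrix.mtx"),
        coo.astype(np.int64) if integer else coo,
        field="integer" if integer else "real",
    )
    with open(os.path.join(mdir, "barcodes.tsv"), "w") as fh:
        fh.writelines(b + "\n" for b in ds.col_annotations["barcode_id"])
    rows = ds.row_annotations
    with open(os.path.join(mdir, "features.tsv"), "w") as fh:
        for _, r in rows.iterrows():
            fields = [str(r["feature_id"])]
            if "symbol" in rows.columns:
                fields.append(str(r["symbol"]))
            if "feature_type" in rows.columns:
                fields.append(str(r["feature_type"]))
            fh.write("\t".join(fields) + "\n")

    positions_path = os.path.join(spatial, POSITIONS_V2)
    cols = ds.col_annotations
    with open(positions_path, "w") as fh:
        fh.write(",".join(POSITION_COLUMNS) + "\n")
        for i in range(ds.n_obs):
            if not ds.coords_valid[i]:
                continue  # flagged-missing spots have no positions row
            fh.write(
                ",".join(
                    [
                        str(cols["barcode_id"].iat[i]),
                        str(int(bool(cols["in_tissue"].iat[i]))),
                        str(int(cols["array_row"].iat[i])),
                        str(int(cols["array_col"].iat[i])),
                        _fmt_pixel(ds.spatial_coords[i, 1]),
                        _fmt_pixel(ds.spatial_coords[i, 0]),
                    ]
                )
                + "\n"
            )

    scalefactors = dict(ds.metadata.get("scalefactors", {}).get(sample_id, {}))
    image_files = {}
    for row in ds.image_table:
        scalefactors[SCALEF_KEYS.get(row.image_id, f"tissue_{row.image_id}_scalef")] = row.scale_factor
        loaded = row.image.realize()
        path = os.path.join(spatial, IMAGE_FILES.get(row.image_id, f"tissue_{row.image_id}_image.png"))
        from PIL import Image

        arr = loaded.pixels
        Image.fromarray(arr[:, :, 0] if arr.shape[2] == 1 else arr).save(path, format="PNG")
        image_files[row.image_id] = path
    scalefactors.setdefault("spot_diameter_fullres", 100.0)
    scalefactors.setdefault("fiducial_diameter_fullres", 150.0)
    scalef_path = os.path.join(spatial, SCALEFACTORS)
    with open(scalef_path, "w") as fh:
        json.dump(scalefactors, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return VisiumBundle(root, mdir, positions_path, "v2_header", scalef_path, image_files)


# ---------------------------------------------------------------------- #
# validator


def validate_bundle(root) -> list:
    """Structural health report for a bundle; problems are findings, not raises.

    Each finding is ``{"code": ..., "message": ...}``.  Zero findings means
    ``read_visium`` will succeed without warnings.  Checked: presence of the
    matrix triplet, a positions file with a well-formed dialect, parseable
    scale factors in (0, 1], and barcode agreement between matrix and
    positions (unmatched counts in either direction are reported).
    """
    findings = []

    def add(code, message, **extra):
        findings.append({"code": code, "message": message, **extra})

    root = str(root)
    mdir = None
    for choice in ("filtered", "raw"):
        cand = os.path.join(root, MATRIX_DIRS[choice])
        if os.path.isdir(cand):
            mdir = cand
            break
    if mdir is None:
        add("MissingFile", f"no raw/filtered feature_bc_matrix directory in {root}")
    else:
        for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
            if _maybe_gz(os.path.join(mdir, name)) is None:
                add("MissingFile", f"missing {name}(.gz) in {mdir}")

    spatial = os.path.join(root, "spatial")
    positions = None
    for name in (POSITIONS_V2, POSITIONS_V1):
        cand = os.path.join(spatial, name)
        if os.path.exists(cand):
            positions = cand
            break
    if positions is None:
        add("MissingFile", f"missing {POSITIONS_V2} / {POSITIONS_V1} in {spatial}")
    else:
        try:
            dialect = detect_positions_dialect(positions)
            pos = _read_positions(positions, dialect)
        except DialectError as exc:
            add("DialectError", str(exc))
            pos = None
        if pos is not None and mdir is not None:
            bc_path = _maybe_gz(os.path.join(mdir, "barcodes.tsv"))
            if bc_path:
                with _open_text(bc_path) as fh:
                    barcodes = {line.strip() for line in fh if line.strip()}
                pos_bc = set(pos["barcode"])
                only_pos = len(pos_bc - barcodes)
                only_mtx = len(barcodes - pos_bc)
                if only_pos:
                    add(
                        "BarcodeMismatch",
                        f"{only_pos} positions barcode(s) not in the matrix",
                        n_unmatched=only_pos,
                    )
                if only_mtx:
                    add(
                        "BarcodeMismatch",
                        f"{only_mtx} matrix barcode(s) without positions",
                        n_unmatched=only_mtx,
                    )

    scalef_path = os.path.join(spatial, SCALEFACTORS)
    if not os.path.exists(scalef_path):
        add("MissingFile", f"missing {SCALEFACTORS} in {spatial}")
    else:
        try:
            with open(scalef_path) as fh:
                scalefactors = json.load(fh)
        except (json.JSONDecodeError, OSError) as exc:
            add("ScaleFactorError", f"{scalef_path}: {exc}")
        else:
            for key in SCALEF_KEYS.values():
                if key in scalefactors and not (0 < scalefactors[key] <= 1):
                    add(
                        "ScaleFactorError",
                        f"{key}={scalefactors[key]} outside (0, 1]",
                    )
    return findings
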