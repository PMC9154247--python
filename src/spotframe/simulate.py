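"""Deterministic synthetic Visium bundles and molecule tables.

Every other module is testable offline against fixtures emitted here, each
accompanied by a ground-truth manifest so checks never have to re-derive
truth from the files they are testing.

The spot lattice follows the Visium hexagonal convention: a spot exists at
(array_row, array_col) iff ``array_col % 2 == array_row % 2``; neighbouring
columns are offset by half a pitch horizontally and rows by pitch * sqrt(3)/2
vertically, then shifted to a positive margin.  Counts are negative binomial
with the mean/dispersion parameterization ``var = mean + mean^2 / dispersion``
(dispersion here is the gamma shape; larger means closer to Poisson), with
the mean halved outside the tissue region.  The tissue region is a
contiguous disk around the lattice centroid covering about the requested
fraction of spots.

One explicitly seeded generator drives everything; the same seed yields a
byte-identical bundle.  No global RNG state is touched.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from PIL import Image

from .errors import ArgumentError
from .visium import (
    IMAGE_FILES,
    MATRIX_DIRS,
    POSITION_COLUMNS,
    POSITIONS_V1,
    POSITIONS_V2,
    SCALEFACTORS,
)

DEFAULT_SAMPLE_ID = "sample01"


@dataclass
class FixtureManifest:
    """Ground truth for one synthetic Visium bundle."""

    seed: int
    n_genes: int
    n_spots: int
    n_in_tissue: int
    total_counts: int
    spot_pitch: float
    tissue_fraction: float
    nb_mean: float
    nb_dispersion: float
    image_dims: dict  # image_id -> [width, height] in that image's pixels
    scale_factors: dict
    spots: list = field(default_factory=list)  # per-spot truth records

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def from_json(path):
        with open(path) as fh:
            return FixtureManifest(**json.load(fh))


def _synthesize_barcodes(rng, n):
    """Unique seeded 16-mers over ACGT, suffixed "-1" like Space Ranger."""
    seen, out = set(), []
    alphabet = np.array(list("ACGT"))
    while len(out) < n:
        bc = "".join(alphabet[rng.integers(0, 4, size=16)]) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _nb_draw(rng, mean, dispersion, size):
    """Negative binomial via gamma-Poisson: var = mean + mean^2/dispersion."""
    lam = rng.gamma(shape=dispersion, scale=np.asarray(mean) / dispersion, size=size)
    return rng.poisson(lam)


def make_visium_fixture(
    root,
    n_array_rows=8,
    n_array_cols=8,
    n_genes=100,
    tissue_fraction=0.5,
    nb_mean=5.0,
    nb_dispersion=2.0,
    spot_pitch=200.0,
    lowres_scalef=0.05,
    seed=0,
) -> FixtureManifest:
    """Write a complete Space Ranger-layout bundle and return its manifest.

    The bundle contains the filtered matrix triplet, the positions table in
    BOTH dialects as sibling files (header ``tissue_positions.csv`` and
    headerless ``tissue_positions_list.csv``), the scale-factor JSON and a
    lowres PNG whose dimensions are ``ceil(fullres extent * scalef)``.
    """
    if n_array_rows <= 0 or n_array_cols <= 0 or n_genes <= 0:
        raise ArgumentError("n_array_rows, n_array_cols and n_genes must be positive")
    if not (0 <= tissue_fraction <= 1):
        raise ArgumentError(f"tissue_fraction must be in [0, 1], got {tissue_fraction}")
    if not (0 < lowres_scalef <= 1):
        raise ArgumentError(f"lowres_scalef must be in (0, 1], got {lowres_scalef}")
    if spot_pitch <= 0 or nb_mean < 0 or nb_dispersion <= 0:
        raise ArgumentError("spot_pitch/nb_dispersion must be positive, nb_mean >= 0")

    rng = np.random.default_rng(seed)

    # hexagonal lattice: matching row/col parity only
    lattice = [
        (r, c)
        for r in range(n_array_rows)
        for c in range(n_array_cols)
        if c % 2 == r % 2
    ]
    n_spots = len(lattice)
    margin = spot_pitch
    pxl_col = np.array([round(c * spot_pitch / 2 + margin) for _, c in lattice], dtype=np.int64)
    pxl_row = np.array(
        [round(r * spot_pitch * math.sqrt(3) / 2 + margin) for r, _ in lattice], dtype=np.int64
    )

    # contiguous tissue disk: the k spots nearest the lattice centroid
    k = int(round(tissue_fraction * n_spots))
    center = np.array([pxl_col.mean(), pxl_row.mean()])
    dist = np.hypot(pxl_col - center[0], pxl_row - center[1])
    order = np.argsort(dist, kind="stable")
    in_tissue = np.zeros(n_spots, dtype=bool)
    in_tissue[order[:k]] = True

    barcodes = _synthesize_barcodes(rng, n_spots)
    mean_per_spot = np.where(in_tissue, nb_mean, nb_mean / 2)
    counts = _nb_draw(
        rng, np.broadcast_to(mean_per_spot, (n_genes, n_spots)), nb_dispersion, (n_genes, n_spots)
    ).astype(np.int64)

    root = str(root)
    mdir = os.path.join(root, MATRIX_DIRS["filtered"])
    spatial = os.path.join(root, "spatial")
    os.makedirs(mdir, exist_ok=True)
    os.makedirs(spatial, exist_ok=True)

    scipy.io.mmwrite(os.path.join(mdir, "matrix.mtx"), sp.coo_matrix(counts), field="integer")
    with open(os.path.join(mdir, "barcodes.tsv"), "w") as fh:
        fh.writelines(b + "\n" for b in barcodes)
    with open(os.path.join(mdir, "features.tsv"), "w") as fh:
        for i in range(n_genes):
            fh.write(f"SYNG{i + 1:05d}\tGene{i + 1:04d}\tGene Expression\n")

    lines = [
        f"{barcodes[i]},{int(in_tissue[i])},{lattice[i][0]},{lattice[i][1]},{pxl_row[i]},{pxl_col[i]}"
        for i in range(n_spots)
    ]
    with open(os.path.join(spatial, POSITIONS_V2), "w") as fh:
        fh.write(",".join(POSITION_COLUMNS) + "\n")
        fh.writelines(line + "\n" for line in lines)
    with open(os.path.join(spatial, POSITIONS_V1), "w") as fh:
        fh.writelines(line + "\n" for line in lines)

    extent_w = float(pxl_col.max() + margin)
    extent_h = float(pxl_row.max() + margin)
    low_w = math.ceil(extent_w * lowres_scalef)
    low_h = math.ceil(extent_h * lowres_scalef)
    tissue_radius = (dist[in_tissue].max() + spot_pitch / 2) if in_tissue.any() else 0.0
    _render_lowres(
        os.path.join(spatial, IMAGE_FILES["lowres"]),
        low_w,
        low_h,
        center * lowres_scalef,
        tissue_radius * lowres_scalef,
    )

    scale_factors = {
        "tissue_lowres_scalef": lowres_scalef,
        "tissue_hires_scalef": min(1.0, lowres_scalef * 4),
        "spot_diameter_fullres": spot_pitch * 0.65,
        "fiducial_diameter_fullres": spot_pitch,
    }
    with open(os.path.join(spatial, SCALEFACTORS), "w") as fh:
        json.dump(scale_factors, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = FixtureManifest(
        seed=int(seed),
        n_genes=int(n_genes),
        n_spots=int(n_spots),
        n_in_tissue=int(in_tissue.sum()),
        total_counts=int(counts.sum()),
        spot_pitch=float(spot_pitch),
        tissue_fraction=float(tissue_fraction),
        nb_mean=float(nb_mean),
        nb_dispersion=float(nb_dispersion),
        image_dims={"lowres": [low_w, low_h]},
        scale_factors=scale_factors,
        spots=[
            {
                "barcode": barcodes[i],
                "array_row": int(lattice[i][0]),
                "array_col": int(lattice[i][1]),
                "in_tissue": bool(in_tissue[i]),
                "pxl_row_in_fullres": int(pxl_row[i]),
                "pxl_col_in_fullres": int(pxl_col[i]),
            }
            for i in range(n_spots)
        ],
    )
    manifest.to_json(os.path.join(root, "manifest.json"))
    return manifest


def _render_lowres(path, width, height, center_xy, radius):
    """Deterministic cartoon histology: pale background, darker tissue disk."""
    yy, xx = np.mgrid[0:height, 0:width]
    inside = (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = 235, 228, 222
    img[inside] = (186, 130, 140)
    Image.fromarray(img).save(path, format="PNG")


# ---------------------------------------------------------------------- #
# molecule fixtures


@dataclass
class MoleculeFixtureManifest:
    """Ground truth for a synthetic molecule record table."""

    seed: int
    n_genes: int
    n_cells: int
    total_molecules: int
    field_w: float
    field_h: float
    sample_id: str
    feature_ids: list
    barcodes: list
    counts: list  # exact per-(gene, cell) matrix, row-major

    def counts_matrix(self):
        return np.asarray(self.counts, dtype=np.int64)


def make_molecule_fixture(
    n_cells=20,
    n_genes=10,
    mean_molecules_per_pair=2.0,
    field_w=1000.0,
    field_h=800.0,
    seed=0,
):
    """Poisson molecule table plus its exact per-pair counts matrix.

    Per (gene, cell) the molecule count is Poisson(mean) and each molecule's
    (x, y) is uniform over ``[0, field_w) x [0, field_h)`` full-resolution
    pixels.  Returns ``(record_table, manifest)``.
    """
    if n_cells <= 0 or n_genes <= 0 or field_w <= 0 or field_h <= 0:
        raise ArgumentError("n_cells, n_genes and field dims must be positive")
    if mean_molecules_per_pair < 0:
        raise ArgumentError("mean_molecules_per_pair must be >= 0")

    rng = np.random.default_rng(seed)
    feature_ids = [f"SYNG{i + 1:05d}" for i in range(n_genes)]
    barcodes = _synthesize_barcodes(rng, n_cells)
    counts = rng.poisson(mean_molecules_per_pair, size=(n_genes, n_cells))

    recs = {"feature_id": [], "sample_id": [], "barcode_id": [], "x": [], "y": []}
    for g in range(n_genes):
        for c in range(n_cells):
            n = int(counts[g, c])
            if n == 0:
                continue
            xs = rng.uniform(0, field_w, size=n)
            ys = rng.uniform(0, field_h, size=n)
            recs["feature_id"].extend([feature_ids[g]] * n)
            recs["sample_id"].extend([DEFAULT_SAMPLE_ID] * n)
            recs["barcode_id"].extend([barcodes[c]] * n)
            recs["x"].extend(xs.tolist())
            recs["y"].extend(ys.tolist())
    table = pd.DataFrame(recs)

    manifest = MoleculeFixtureManifest(
        seed=int(seed),
        n_genes=int(n_genes),
        n_cells=int(n_cells),
        total_molecules=int(counts.sum()),
        field_w=float(field_w),
        field_h=float(field_h),
        sample_id=DEFAULT_SAMPLE_ID,
        feature_ids=feature_ids,
        barcodes=barcodes,
        counts=counts.astype(int).tolist(),
    )
    return table, manifest


def molecule_fixture_dataset(manifest: MoleculeFixtureManifest):
    """Build the cell-level dataset implied by a molecule fixture manifest."""
    from .core import SpatialDataset

    counts = manifest.counts_matrix()
    rows = pd.DataFrame({"feature_id": manifest.feature_ids})
    cols = pd.DataFrame(
        {"barcode_id": manifest.barcodes, "sample_id": manifest.sample_id}
    )
    return SpatialDataset({"counts": counts}, row_annotations=rows, col_annotations=cols)
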