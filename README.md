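# spotframe

**spotframe** is data infrastructure for spatially-resolved transcriptomics
(SRT) in Python: an annotated feature-by-observation container extended with
spatial coordinates, sample-linked histology images and a ragged
molecule-level store, together with a bit-exact 10x Genomics Visium
Space Ranger reader/writer, a deterministic synthetic-bundle generator and
spot/molecule visualization.

It is aimed at analysts and method developers who need a common, workflow-
independent object for SRT data: one structure that downstream tools can
slice, combine and serialize without each reinventing the Space Ranger
parsing, the (sample, barcode) identity rules, or the scale-factor
bookkeeping that links spot coordinates to downsampled images.

## The data model

A `SpatialDataset` holds, for `n` features (genes) and `m` observations
(spots or cells):

* **assays** — named `n x m` numeric matrices (dense or sparse); the
  canonical first assay is `counts`;
* **row_annotations** — a table of feature metadata with a unique
  `feature_id` (and optionally `symbol`);
* **col_annotations** — observation metadata with `barcode_id` and
  `sample_id`; for Visium data also `in_tissue`, `array_row`, `array_col`.
  Observation identity is the *pair* `(sample_id, barcode_id)` — Visium
  barcodes recur across capture areas;
* **reduced_dims** — named `m x k` embeddings;
* **spatial_coords** — an `m x d` matrix (`d >= 2`) with named axes,
  default `("pxl_col_in_fullres", "pxl_row_in_fullres")`, in
  full-resolution image pixels, y increasing downward.  Observations with
  unknown positions carry an explicit validity flag instead of silent NaNs;
* **image_table** — rows of `(sample_id, image_id, scale_factor, image)`,
  where an image is in-memory, a local path loaded on demand, or a URL
  fetched on demand.  A point `x` in full-resolution pixels maps to a
  downsampled image as `x * scale_factor`;
* **molecules** — for in-situ platforms (seqFISH-style), a `MoleculeStore`
  of per-molecule records `(feature_id, sample_id, barcode_id, x, y[, z])`
  grouped per (feature, observation), consistent with `counts`.

Every operation — accessors, replacement, subsetting, multi-sample
`combine` — slices or concatenates *all* components consistently, and every
returned dataset passes full validation.

## Worked example

```python
import spotframe as sf

# a synthetic Space Ranger bundle with known ground truth
manifest = sf.make_visium_fixture(
    "demo_bundle", n_array_rows=8, n_array_cols=8, n_genes=100,
    tissue_fraction=0.5, seed=0,
)
print(manifest.n_spots, manifest.n_in_tissue, manifest.total_counts)
# 32 16 12402

ds = sf.read_visium("demo_bundle")
print(ds)
# <SpatialDataset 100 features x 32 obs, assays=['counts'],
#  samples=['sample01'],
#  coords=['pxl_col_in_fullres', 'pxl_row_in_fullres'], images=1>

summary = sf.plot_spots(dataset=ds, output="spots.png",
                        in_tissue_only=True, frame="image:lowres")
print(summary["n_points"], summary["bbox"])
# 16 [10.0, 45.0, 27.3, 61.95]
```

The 8x8 hexagonal lattice has 32 spots (parity rule
`array_col % 2 == array_row % 2`), half of which fall inside the simulated
tissue disk; the reader recovers exactly the simulated totals, and the
lowres-frame plot draws the 16 in-tissue spots inside the 55x81-pixel
image (coordinates above are image pixels after scaling by the lowres
scale factor 0.05).

A round trip through the writer is exact:

```python
sf.write_bundle(ds, "demo_rewritten")
assert sf.dataset_differences(ds, sf.read_visium("demo_rewritten")) == []
```

## Command line

```bash
spotframe simulate --rows 8 --cols 8 --genes 100 --seed 0 --out demo_bundle
spotframe convert  --in demo_bundle --out normalized   # rewrites, v2 dialect
spotframe validate --in demo_bundle                    # findings as JSON
spotframe summarize --in demo_bundle
```

Exit codes: 0 success, 1 validation findings, 2 usage error, 3 missing
input.

## Scope

On-disk/backed matrices, HDF5 Space Ranger output, Visium HD, cell
segmentation, molecule-to-cell assignment, image registration and
downstream analysis methods are out of scope; see `docs/methods.md` for the
design rationale and limitations.
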