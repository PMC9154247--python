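# Methods

## The container and its invariants

`SpatialDataset` follows the annotated-experiment convention of genomics
infrastructure: features on rows, observations on columns, with every
auxiliary component keyed to one of those two axes.  The invariants enforced
on every construction (and re-checked after every replacement, subset or
combine) are:

* all assays share one `(n_features, n_obs)` shape; annotation tables have
  matching row counts; every reduced-dimension entry has `n_obs` rows;
* `feature_id` is unique; `(sample_id, barcode_id)` is unique.  Barcode
  uniqueness is deliberately *not* required on its own, because Visium
  barcode sequences are reused across capture areas — sample identity is
  part of observation identity;
* `spatial_coords` has `n_obs` rows and either zero or at least two named
  axes.  Coordinates are full-resolution image pixels, y-down.  An
  observation without a known position carries `coords_valid == False`; a
  non-finite coordinate on an unflagged observation is a validation error,
  never a silent NaN.  This keeps "is this spot mappable?" decidable
  without sentinel conventions;
* every `sample_id` in the image table occurs among the observations
  (no orphaned images).

Validation collects all findings before raising.  Homogeneous findings
raise the specific error class (`DimensionMismatch`, `DuplicateKey`,
`OrphanImage`); mixed findings raise `ValidationError` carrying the full
list, so a caller fixing a malformed input sees every problem at once.

Subsetting accepts integer lists, boolean masks or ID lists, preserves
selector order, slices all components, drops image rows whose sample
vanished and restricts an attached molecule store.  Feature subsetting
leaves reduced dimensions untouched — embeddings are observation-level
objects and do not index features.  `combine` requires an identical
`feature_id` sequence across inputs: implicit intersection or union would
silently reorder data, a classic source of wrong-gene bugs, so alignment is
the caller's explicit job.  Under `suffix_on_clash`, the n-th reuse of a
sample id becomes `id.n`, applied consistently to observation annotations,
image rows and molecule records.  Combining also requires identical assay
names and reduced-dimension names; reduced dimensions are row-concatenated.

## Molecule-level storage

For molecule-based platforms the per-(gene, cell) data is ragged: a
variable-length list of molecule coordinates.  `MoleculeStore` keeps the
flat record table plus a hash index from `(feature_id, (sample_id,
barcode_id))` to row positions, so group lookup is O(1) in the group count
and the original records (including any extra columns) survive round trips
bit-exact.  The owning dataset defines the legal universe: pairs without
records are *empty* groups, and records naming unknown features or
observations are errors.  `counts_from_molecules` materializes the group
sizes as an integer matrix; on fixture data it equals the generator's exact
counts matrix, and dataset subsetting drops exactly the corresponding
groups.  Molecules unassigned to any cell are outside the contract: loaders
must filter them first (no "unassigned" pseudo-observation exists, which
keeps the identity invariants unconditional).  Molecule coordinates share
the full-resolution pixel frame of the spot/cell coordinates.

## Images

Three storage modes — `loaded` (pixels in memory), `stored` (local path),
`remote` (URL) — with two contractual properties: *laziness* (constructing
a stored/remote entry performs zero reads; verified in tests by deleting
the source after construction) and *memoized realization* (the first
`realize()` decodes and caches; later calls, and plotting, never re-fetch).
`file://` URLs are accepted alongside http/https so the remote path is
testable offline.  Codecs are PNG, JPEG and TIFF; anything else raises
`UnreadableSource` naming the codec.  Pixel layout is row-major, origin
top-left, y-down; this single convention statement forces the y-axis
inversion in plots.  `map_fullres_to_image` is plain multiplication by the
scale factor with no rounding — rounding happens only at draw time.  One
scale factor per image row, so hires and lowres of the same sample can
differ.

## Visium Space Ranger IO

The reader consumes the Matrix Market triplet (each of the three files
independently gzipped or not, detected by suffix), the positions CSV in
either dialect and the scale-factor JSON.  Dialect detection is
content-based: a first cell equal to the literal `barcode` means the
headered (v2) file, anything else the headerless (v1) file; both must have
six columns.  The source columns store `(pxl_row, pxl_col)`; the dataset's
axis order is `(pxl_col, pxl_row)` so that axis 0 is horizontal and spot
overlays need no transposition — stated here once because it is the one
place the column order flips.  Matrix barcodes missing from the positions
file (possible with the raw matrix) get flagged-missing coordinates,
`in_tissue=False` and lattice indices −1 (an impossible index); positions
rows missing from the matrix are ignored with a logged count; a *total*
mismatch raises `BarcodeJoinError`, since it almost always means the wrong
directory was paired with the matrix.  The default `data_choice` is
`filtered`, the usual analysis entry point.

The writer emits the v2 dialect, integer Matrix Market values whenever the
assay is integral, and positions rows only for coordinate-valid
observations; integer pixel values are written as integers so the
read-write-read cycle is bit-exact.  `validate_bundle` reports findings
(missing files, dialect problems, barcode mismatch counts, scale factors
outside (0, 1]) rather than raising; zero findings coincides with a
warning-free read.

## The synthetic generator

The fixture generator emulates the *structure* of Space Ranger output, not
tissue biology: a hexagonal lattice (spots where
`array_col % 2 == array_row % 2`, columns offset by pitch/2, rows by
pitch·√3/2, shifted to a one-pitch margin and rounded to integer pixels), a
contiguous tissue disk covering the requested fraction of spots (the k
spots nearest the lattice centroid), and negative-binomial counts with the
mean/dispersion parameterization `var = mean + mean²/dispersion`
(gamma-Poisson mixture; stated explicitly because "dispersion" is
ambiguous across conventions), with the mean halved outside the tissue.
Defaults — 8×8 array, 100 genes, pitch 200 px, `nb_mean` 5, dispersion 2,
lowres scale factor 0.05 — give a desk-scale bundle whose lowres image is a
few kilobytes.  Barcodes are seeded 16-mers over ACGT suffixed `-1`,
unique by construction check.  One explicitly seeded generator drives
everything and no global RNG state is touched, so a seed fixes the bundle
byte-for-byte.  Both positions dialects are written as siblings (the reader
prefers v2), and the manifest records the full per-spot truth table so
every reader-level check can be phrased against the manifest without
re-deriving truth from the files under test.

What passing tests on these fixtures do *not* show: real bundles have
irregular tissue boundaries, spatially structured expression, saturation
and hires images; none of that affects the container/IO contracts tested
here, but statistical conclusions about real data cannot be drawn from the
generator.

## Visualization

Plots return a machine-checkable *layer summary* (point count, bounding
box, color-scale type, marker size and its provenance, top-most barcode)
and tests assert on summaries, never on rendered bytes — font and
antialiasing variance makes pixel comparison brittle across platforms.
Continuous color is used for feature values and numeric annotations,
a categorical palette for everything else.  Marker size defaults to
`spot_diameter_fullres × scale_factor` when the metadata and an image frame
provide it, else a fixed fallback; the summary records which.  In image
frames the y axis is inverted (y-down), so the spot with the smallest
`pxl_row` is drawn top-most.

## Numerical and engineering choices

* Integer counts stay integers end-to-end (Matrix Market `integer` field,
  int64 in memory); equality checks in tests are exact, not approximate.
* Pixel coordinates in fixtures are integers, making CSV round trips
  bit-exact by construction; the writer falls back to `repr` (shortest
  round-trip form) for genuinely fractional coordinates.
* Sparse assays are kept sparse through subsetting and combining (CSR);
  dense inputs stay dense.
* Degenerate inputs handled explicitly: zero-column coordinate matrices
  (non-spatial use), empty molecule tables (all-zero counts), all-zero
  library sizes in the QC histogram, `tissue_fraction` 0 and 1.
* Problem sizes in the test and acceptance workloads (lattices up to
  16×16, 10⁴ molecule records, 20 round-trip seeds, 50 random datasets for
  the subset algebra) were chosen as the smallest scales at which the
  contracts are non-trivial — e.g. ≥10⁴ negative-binomial draws so a
  5-standard-error band around the mean is a meaningful test.

## Known limitations

Backed/out-of-core matrices, HDF5 Space Ranger matrices, Visium HD, probe
sets, image registration/transforms, 3-D beyond allowing extra named axes,
and molecule-to-cell assignment are out of scope.  `set_component` returns
a new dataset but does not deep-copy matrices; callers mutating a shared
matrix in place bypass validation.  Barcode-ID selection in `subset`
requires the barcode to be unique across samples (use boolean masks or
explicit `(sample_id, barcode_id)` logic otherwise).
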