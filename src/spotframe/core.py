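"""The annotated feature-by-observation container with spatial extensions.

:class:`SpatialDataset` holds named assay matrices (features x observations),
per-feature and per-observation annotation tables, reduced-dimension
embeddings, an observation-by-d spatial coordinate matrix with named axes,
and a table of sample-linked images.  It is the Python analog of the
annotated-experiment containers common in genomics: every operation slices or
concatenates all components consistently, and every returned dataset passes
full validation.

Conventions
-----------
* Rows are features, columns are observations (spots or cells).
* Observation identity is the pair ``(sample_id, barcode_id)``; barcodes
  recur across capture areas so barcodes alone are not unique.
* Spatial coordinates are in full-resolution image pixels, y increasing
  downward.  Observations with unknown coordinates carry an explicit
  ``coords_valid == False`` flag rather than bare NaN sentinels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
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
from .images import ImageTable

DEFAULT_SAMPLE_ID = "sample01"
DEFAULT_COORD_NAMES = ("pxl_col_in_fullres", "pxl_row_in_fullres")

_COMPONENTS = (
    "assay",
    "row_annotations",
    "col_annotations",
    "reduced_dim",
    "spatial_coords",
    "spatial_coords_names",
    "image_table",
    "sample_ids",
)


def _is_matrix(x):
    return sp.issparse(x) or isinstance(x, np.ndarray)


class SpatialDataset:
    """Annotated spatial omics container.

    Parameters
    ----------
    assays
        A single feature-by-observation matrix (named ``"counts"``) or a dict
        of named matrices sharing one shape.  Dense ndarray or scipy sparse.
    row_annotations
        DataFrame with one row per feature; must (or will, by default) carry
        a unique string ``feature_id`` column.
    col_annotations
        DataFrame with one row per observation carrying ``barcode_id`` and
        ``sample_id`` (a single default sample is injected when absent).
    spatial_coords
        ``(n_obs, d)`` numeric array, ``d >= 2`` when non-empty.
    spatial_coords_names
        Axis names, length d.  Default Visium names when d == 2.
    coords_valid
        Boolean flag per observation; defaults to "row is all-finite".
    reduced_dims
        Dict of name -> ``(n_obs, k)`` arrays.
    image_table
        :class:`~spotframe.images.ImageTable`; every referenced sample_id
        must appear among the observations.
    metadata
        Free-form dict (e.g. per-sample scale-factor JSON); carried along.
    """

    def __init__(
        self,
        assays,
        row_annotations=None,
        col_annotations=None,
        spatial_coords=None,
        spatial_coords_names=None,
        coords_valid=None,
        reduced_dims=None,
        image_table=None,
        molecules=None,
        metadata=None,
        validate=True,
    ):
        if _is_matrix(assays):
            assays = {"counts": assays}
        if not isinstance(assays, dict) or not assays:
            raise DimensionMismatch("at least one assay is required")
        self._assays = dict(assays)
        first = next(iter(self._assays.values()))
        n_features, n_obs = first.shape

        if row_annotations is None:
            row_annotations = pd.DataFrame(
                {"feature_id": [f"feature{i + 1:04d}" for i in range(n_features)]}
            )
        if col_annotations is None:
            col_annotations = pd.DataFrame(
                {"barcode_id": [f"obs{i + 1:04d}" for i in range(n_obs)]}
            )
        col_annotations = col_annotations.reset_index(drop=True).copy()
        row_annotations = row_annotations.reset_index(drop=True).copy()
        if "sample_id" not in col_annotations.columns:
            col_annotations["sample_id"] = DEFAULT_SAMPLE_ID
        self._rows = row_annotations
        self._cols = col_annotations

        if spatial_coords is None:
            spatial_coords = np.zeros((n_obs, 0), dtype=float)
        spatial_coords = np.asarray(spatial_coords, dtype=float)
        if spatial_coords.ndim != 2:
            raise DimensionMismatch("spatial_coords must be a 2-D matrix")
        if spatial_coords_names is None:
            if spatial_coords.shape[1] == 2:
                spatial_coords_names = DEFAULT_COORD_NAMES
            else:
                spatial_coords_names = tuple(
                    f"dim{i + 1}" for i in range(spatial_coords.shape[1])
                )
        self._coords = spatial_coords
        self._coord_names = tuple(str(n) for n in spatial_coords_names)

        if coords_valid is None:
            coords_valid = np.isfinite(spatial_coords).all(axis=1)
        self._coords_valid = np.asarray(coords_valid, dtype=bool)

        self._reduced = dict(reduced_dims) if reduced_dims else {}
        self._images = image_table if image_table is not None else ImageTable()
        self.molecules = molecules
        self.metadata = dict(metadata) if metadata else {}

        if validate:
            _raise_findings(self._validate())

    # ------------------------------------------------------------------ #
    # validation

    def _validate(self):
        findings = []
        shapes = {name: a.shape for name, a in self._assays.items()}
        n_features, n_obs = next(iter(shapes.values()))
        for name, shape in shapes.items():
            if not name or not isinstance(name, str):
                findings.append((DimensionMismatch, f"assay name {name!r} must be a nonempty string"))
            if shape != (n_features, n_obs):
                findings.append(
                    (DimensionMismatch, f"assay {name!r} has shape {shape}, expected {(n_features, n_obs)}")
                )
        if len(self._rows) != n_features:
            findings.append(
                (DimensionMismatch, f"row_annotations has {len(self._rows)} rows, expected {n_features}")
            )
        if len(self._cols) != n_obs:
            findings.append(
                (DimensionMismatch, f"col_annotations has {len(self._cols)} rows, expected {n_obs}")
            )
        if "feature_id" not in self._rows.columns:
            findings.append((DimensionMismatch, "row_annotations lacks a feature_id column"))
        else:
            fids = self._rows["feature_id"]
            if fids.duplicated().any():
                dupes = sorted(fids[fids.duplicated()].unique().tolist())
                findings.append((DuplicateKey, f"duplicated feature_id: {dupes[:5]}"))
        for col in ("barcode_id", "sample_id"):
            if col not in self._cols.columns:
                findings.append((DimensionMismatch, f"col_annotations lacks a {col} column"))
        if {"barcode_id", "sample_id"} <= set(self._cols.columns):
            pairs = self._cols[["sample_id", "barcode_id"]]
            if pairs.duplicated().any():
                d = pairs[pairs.duplicated()].apply(tuple, axis=1).unique().tolist()
                findings.append((DuplicateKey, f"duplicated (sample_id, barcode_id): {d[:5]}"))
        for name, rd in self._reduced.items():
            if np.asarray(rd).shape[0] != n_obs:
                findings.append(
                    (DimensionMismatch, f"reduced_dim {name!r} has {np.asarray(rd).shape[0]} rows, expected {n_obs}")
                )
        if self._coords.shape[0] != n_obs:
            findings.append(
                (DimensionMismatch, f"spatial_coords has {self._coords.shape[0]} rows, expected {n_obs}")
            )
        if self._coords.shape[1] not in (0,) and self._coords.shape[1] < 2:
            findings.append((DimensionMismatch, "spatial_coords needs d >= 2 axes (or none at all)"))
        if len(self._coord_names) != self._coords.shape[1]:
            findings.append(
                (DimensionMismatch, f"{len(self._coord_names)} axis names for {self._coords.shape[1]} coordinate axes")
            )
        if self._coords_valid.shape != (n_obs,) and self._coords.shape[0] == n_obs:
            findings.append((DimensionMismatch, "coords_valid length differs from n_obs"))
        elif self._coords.shape[0] == n_obs and self._coords.size:
            bad = ~np.isfinite(self._coords).all(axis=1) & self._coords_valid
            if bad.any():
                findings.append(
                    (DimensionMismatch, f"{int(bad.sum())} observation(s) have non-finite coordinates but are not flagged missing")
                )
        if "sample_id" in self._cols.columns:
            known = set(self._cols["sample_id"])
            orphans = sorted({s for s in self._images.sample_ids if s not in known})
            if orphans:
                findings.append((OrphanImage, f"image_table sample_id(s) {orphans} absent from col_annotations"))
        return findings

    # ------------------------------------------------------------------ #
    # basic properties

    @property
    def shape(self):
        return next(iter(self._assays.values())).shape

    @property
    def n_features(self):
        return self.shape[0]

    @property
    def n_obs(self):
        return self.shape[1]

    @property
    def assay_names(self):
        return tuple(self._assays)

    @property
    def feature_ids(self):
        return self._rows["feature_id"].tolist()

    @property
    def row_annotations(self):
        return self._rows

    @property
    def col_annotations(self):
        return self._cols

    @property
    def spatial_coords(self):
        return self._coords

    @property
    def spatial_coords_names(self):
        return self._coord_names

    @property
    def coords_valid(self):
        return self._coords_valid

    @property
    def reduced_dim_names(self):
        return tuple(self._reduced)

    @property
    def image_table(self):
        return self._images

    @property
    def sample_ids(self):
        """De-duplicated sample ids in order of first appearance."""
        return tuple(dict.fromkeys(self._cols["sample_id"]))

    @property
    def obs_keys(self):
        """(sample_id, barcode_id) pair per observation, dataset order."""
        return list(zip(self._cols["sample_id"], self._cols["barcode_id"]))

    def assay(self, name="counts"):
        if name == "molecules" and self.molecules is not None:
            return self.molecules
        if name not in self._assays:
            raise UnknownEntry(f"no assay {name!r}; have {list(self._assays)}")
        return self._assays[name]

    def reduced_dim(self, name):
        if name not in self._reduced:
            raise UnknownEntry(f"no reduced_dim {name!r}; have {list(self._reduced)}")
        return self._reduced[name]

    def __repr__(self):
        return (
            f"<SpatialDataset {self.n_features} features x {self.n_obs} obs, "
            f"assays={list(self._assays)}, samples={list(self.sample_ids)}, "
            f"coords={list(self._coord_names)}, images={len(self._images)}>"
        )

    # ------------------------------------------------------------------ #
    # generic accessor / replacement

    def get_component(self, component_name, entry_name=None):
        """Uniform accessor over the container's components.

        ``component_name`` is one of assay, row_annotations, col_annotations,
        reduced_dim, spatial_coords, spatial_coords_names, image_table,
        sample_ids; assay/reduced_dim require ``entry_name``.
        """
        if component_name not in _COMPONENTS:
            raise UnknownComponent(f"{component_name!r} not in {_COMPONENTS}")
        if component_name == "assay":
            return self.assay(entry_name)
        if component_name == "reduced_dim":
            return self.reduced_dim(entry_name)
        return getattr(self, component_name)

    def set_component(self, component_name, value, entry_name=None):
        """Return a dataset with one component replaced; validation re-runs."""
        if component_name == "assay":
            assays = dict(self._assays)
            assays[entry_name] = value
            return self._replace(assays=assays)
        if component_name == "reduced_dim":
            reduced = dict(self._reduced)
            reduced[entry_name] = value
            return self._replace(reduced_dims=reduced)
        if component_name == "spatial_coords":
            value = np.asarray(value, dtype=float)
            names = self._coord_names
            if value.shape[1] != len(names):
                names = None  # let the constructor pick defaults for new d
            return self._replace(spatial_coords=value, spatial_coords_names=names, coords_valid=None)
        if component_name == "spatial_coords_names":
            return self._replace(spatial_coords_names=tuple(value))
        if component_name in ("row_annotations", "col_annotations", "image_table"):
            return self._replace(**{component_name: value})
        raise UnknownComponent(f"cannot set component {component_name!r}")

    def _replace(self, **kw):
        args = dict(
            assays=self._assays,
            row_annotations=self._rows,
            col_annotations=self._cols,
            spatial_coords=self._coords,
            spatial_coords_names=self._coord_names,
            coords_valid=self._coords_valid,
            reduced_dims=self._reduced,
            image_table=self._images,
            molecules=self.molecules,
            metadata=self.metadata,
        )
        args.update(kw)
        return SpatialDataset(**args)

    # ------------------------------------------------------------------ #
    # subsetting

    def _resolve_features(self, selector):
        return _resolve(selector, self.n_features, self.feature_ids, "feature")

    def _resolve_obs(self, selector):
        return _resolve(selector, self.n_obs, self._cols["barcode_id"].tolist(), "observation")

    def subset(self, features=None, obs=None):
        """Slice every component consistently.

        Selectors are integer-index lists, boolean masks, or ID lists
        (feature_id for rows, barcode_id for columns — barcode ID selection
        requires the barcode to be unique in the dataset).  ``None`` keeps
        the axis untouched.  Retained order follows the selector.  Image rows
        whose sample disappears are dropped; an attached molecule store is
        restricted to the retained (feature, observation) universe.
        """
        fidx = self._resolve_features(features)
        oidx = self._resolve_obs(obs)

        assays = {name: _slice_matrix(a, fidx, oidx) for name, a in self._assays.items()}
        rows = self._rows.iloc[fidx].reset_index(drop=True)
        cols = self._cols.iloc[oidx].reset_index(drop=True)
        coords = self._coords[oidx]
        valid = self._coords_valid[oidx]
        reduced = {name: np.asarray(rd)[oidx] for name, rd in self._reduced.items()}
        images = self._images.restrict_to_samples(set(cols["sample_id"]))

        molecules = None
        if self.molecules is not None:
            keep_features = rows["feature_id"].tolist()
            keep_obs = list(zip(cols["sample_id"], cols["barcode_id"]))
            molecules = self.molecules.restricted(keep_features, keep_obs)

        return SpatialDataset(
            assays,
            row_annotations=rows,
            col_annotations=cols,
            spatial_coords=coords,
            spatial_coords_names=self._coord_names,
            coords_valid=valid,
            reduced_dims=reduced,
            image_table=images,
            molecules=molecules,
            metadata=self.metadata,
        )

    def __getitem__(self, key):
        features, obs = key if isinstance(key, tuple) else (key, None)
        return self.subset(features=features, obs=obs)


# ---------------------------------------------------------------------- #
# combination


def combine(datasets, sample_id_policy="require_unique"):
    """Concatenate datasets observation-wise into one multi-sample dataset.

    All inputs must share an identical feature_id sequence (no implicit
    intersection — align first).  Under ``require_unique`` a repeated
    sample_id raises :class:`SampleClash`; under ``suffix_on_clash`` the
    clashing ids get ``.1``, ``.2``, ... appended, consistently across
    observation annotations, the image table and any molecule store.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("combine() needs at least one dataset")
    if sample_id_policy not in ("require_unique", "suffix_on_clash"):
        raise ValueError(f"unknown sample_id_policy {sample_id_policy!r}")

    ref = datasets[0]
    for i, ds in enumerate(datasets[1:], start=2):
        if ds.feature_ids != ref.feature_ids:
            raise FeatureMismatch(
                f"dataset {i} has a different feature_id sequence; align features first"
            )
        if ds.assay_names != ref.assay_names:
            raise DimensionMismatch(
                f"dataset {i} assay names {ds.assay_names} != {ref.assay_names}"
            )
        if set(ds.reduced_dim_names) != set(ref.reduced_dim_names):
            raise DimensionMismatch(
                f"dataset {i} reduced_dims {ds.reduced_dim_names} != {ref.reduced_dim_names}"
            )
        if ds.spatial_coords.shape[1] != ref.spatial_coords.shape[1]:
            raise DimensionMismatch("spatial coordinate dimensionality differs across datasets")
        if ds.spatial_coords_names != ref.spatial_coords_names:
            raise DimensionMismatch(
                f"coordinate axis names differ: {ds.spatial_coords_names} vs {ref.spatial_coords_names}"
            )

    taken: set = set()
    renamed_cols, renamed_images, renamed_stores = [], [], []
    for ds in datasets:
        mapping = {}
        for sid in dict.fromkeys(ds.col_annotations["sample_id"]):
            if sid in taken:
                if sample_id_policy == "require_unique":
                    raise SampleClash(f"sample_id {sid!r} appears in more than one dataset")
                k = 1
                while f"{sid}.{k}" in taken:
                    k += 1
                mapping[sid] = f"{sid}.{k}"
                taken.add(mapping[sid])
            else:
                taken.add(sid)
        cols = ds.col_annotations.copy()
        if mapping:
            cols["sample_id"] = cols["sample_id"].map(lambda s: mapping.get(s, s))
        renamed_cols.append(cols)
        renamed_images.append(ds.image_table.renamed(mapping) if mapping else ds.image_table)
        if ds.molecules is not None:
            renamed_stores.append(ds.molecules.renamed_samples(mapping) if mapping else ds.molecules)
        else:
            renamed_stores.append(None)

    assays = {}
    for name in ref.assay_names:
        mats = [ds.assay(name) for ds in datasets]
        if any(sp.issparse(m) for m in mats):
            assays[name] = sp.hstack([sp.csr_matrix(m) for m in mats], format="csr")
        else:
            assays[name] = np.hstack(mats)

    cols = pd.concat(renamed_cols, ignore_index=True)
    coords = np.vstack([ds.spatial_coords for ds in datasets])
    valid = np.concatenate([ds.coords_valid for ds in datasets])
    reduced = {
        name: np.vstack([np.asarray(ds.reduced_dim(name)) for ds in datasets])
        for name in ref.reduced_dim_names
    }
    images = ImageTable.concat(renamed_images)

    molecules = None
    if all(s is not None for s in renamed_stores) and renamed_stores:
        from .molecules import MoleculeStore

        molecules = MoleculeStore.concat(renamed_stores)

    metadata = {}
    for ds in datasets:
        for key, val in ds.metadata.items():
            if key == "scalefactors" and isinstance(val, dict):
                metadata.setdefault("scalefactors", {}).update(val)
            else:
                metadata.setdefault(key, val)

    return SpatialDataset(
        assays,
        row_annotations=ref.row_annotations,
        col_annotations=cols,
        spatial_coords=coords,
        spatial_coords_names=ref.spatial_coords_names,
        coords_valid=valid,
        reduced_dims=reduced,
        image_table=images,
        molecules=molecules,
        metadata=metadata,
    )


# ---------------------------------------------------------------------- #
# helpers


def _raise_findings(findings):
    if not findings:
        return
    classes = {cls for cls, _ in findings}
    if len(classes) == 1:
        raise next(iter(classes))("; ".join(m for _, m in findings))
    raise ValidationError(findings)


def _resolve(selector, n, ids, axis):
    """Normalize a selector to an integer index array over an axis of size n."""
    if selector is None:
        return np.arange(n)
    if isinstance(selector, slice):
        return np.arange(n)[selector]
    arr = np.asarray(selector)
    if arr.dtype == bool:
        if arr.shape != (n,):
            raise SelectorOutOfRange(f"boolean {axis} mask of length {arr.shape}, expected ({n},)")
        return np.flatnonzero(arr)
    if arr.dtype.kind in "iu":
        if arr.size and (arr.min() < -n or arr.max() >= n):
            raise SelectorOutOfRange(f"{axis} index out of range for axis of size {n}")
        return arr % n if arr.size else arr.astype(int)
    # ID list
    lookup = {}
    for i, val in enumerate(ids):
        lookup.setdefault(val, []).append(i)
    out = []
    for val in np.asarray(selector, dtype=object):
        hits = lookup.get(val)
        if not hits:
            raise UnknownID(f"unknown {axis} ID {val!r}")
        if len(hits) > 1:
            raise UnknownID(f"{axis} ID {val!r} is ambiguous ({len(hits)} occurrences)")
        out.append(hits[0])
    return np.asarray(out, dtype=int)


def _slice_matrix(m, fidx, oidx):
    if sp.issparse(m):
        return m.tocsr()[fidx][:, oidx]
    return np.asarray(m)[np.ix_(fidx, oidx)]


def dataset_differences(a, b, atol=0.0):
    """Component-wise comparison; returns a list of human-readable diffs.

    Empty list means the datasets are equal: same assay names and values
    (exact when ``atol`` is 0), identical annotation tables, bit-equal
    coordinates, axis names, validity flags, reduced dims, and image tables
    matching on (sample_id, image_id, scale_factor).
    """
    diffs = []
    if a.shape != b.shape:
        return [f"shape {a.shape} != {b.shape}"]
    if a.assay_names != b.assay_names:
        diffs.append(f"assay names {a.assay_names} != {b.assay_names}")
    else:
        for name in a.assay_names:
            am, bm = a.assay(name), b.assay(name)
            am = am.toarray() if sp.issparse(am) else np.asarray(am)
            bm = bm.toarray() if sp.issparse(bm) else np.asarray(bm)
            if atol == 0.0:
                ok = np.array_equal(am, bm)
            else:
                ok = np.allclose(am, bm, atol=atol, rtol=0)
            if not ok:
                diffs.append(f"assay {name!r} values differ")
    for label, ta, tb in (
        ("row_annotations", a.row_annotations, b.row_annotations),
        ("col_annotations", a.col_annotations, b.col_annotations),
    ):
        ca, cb = sorted(ta.columns), sorted(tb.columns)
        if ca != cb:
            diffs.append(f"{label} columns {ca} != {cb}")
        elif not ta[ca].reset_index(drop=True).equals(tb[ca].reset_index(drop=True)):
            diffs.append(f"{label} values differ")
    if a.spatial_coords_names != b.spatial_coords_names:
        diffs.append(f"coord names {a.spatial_coords_names} != {b.spatial_coords_names}")
    if not np.array_equal(a.spatial_coords, b.spatial_coords, equal_nan=True):
        diffs.append("spatial_coords differ")
    if not np.array_equal(a.coords_valid, b.coords_valid):
        diffs.append("coords_valid flags differ")
    if set(a.reduced_dim_names) != set(b.reduced_dim_names):
        diffs.append(f"reduced dims {a.reduced_dim_names} != {b.reduced_dim_names}")
    else:
        for name in a.reduced_dim_names:
            if not np.allclose(np.asarray(a.reduced_dim(name)), np.asarray(b.reduced_dim(name))):
                diffs.append(f"reduced_dim {name!r} differs")
    ia = [(r.sample_id, r.image_id, r.scale_factor) for r in a.image_table]
    ib = [(r.sample_id, r.image_id, r.scale_factor) for r in b.image_table]
    if ia != ib:
        diffs.append(f"image tables differ: {ia} != {ib}")
    return diffs
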