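"""Spot- and molecule-level spatial plotting.

Figures are rendered with matplotlib to the file format implied by the
output suffix (png/pdf/svg).  Every plotting call also returns a *layer
summary* — point count, coordinate bounding box, color-scale type,
marker size, top-most barcode — so tests and pipelines can assert on what
was drawn without comparing pixels.

Convention: plots use the image coordinate frame, y increasing downward, so
a spot with the smallest ``pxl_row`` appears at the top.  Image frames
(``frame="image:<image_id>"``) first map full-resolution coordinates by the
image's scale factor and underlay the realized image.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptySelection, NoSuchImage, UnknownColorBy, UnknownFeature
from .images import map_fullres_to_image
from .molecules import molecules_of, require_store

FALLBACK_MARKER_SIZE = 6.0


@dataclass
class PlotSpec:
    """Declarative description of a spot plot."""

    dataset: object
    output: str
    sample_id: str | None = None
    color_by: str | None = None
    frame: str = "fullres"
    in_tissue_only: bool = False


def plot_spots(spec=None, **kwargs) -> dict:
    """Render one marker per spot in the chosen coordinate frame.

    Accepts a :class:`PlotSpec` or its fields as keyword arguments.  Returns
    the layer summary dict.
    """
    if spec is None:
        spec = PlotSpec(**kwargs)
    ds = spec.dataset
    sample_id = _default_sample(ds, spec.sample_id)

    mask = (ds.col_annotations["sample_id"] == sample_id).to_numpy()
    mask &= ds.coords_valid
    if spec.in_tissue_only:
        if "in_tissue" not in ds.col_annotations.columns:
            raise UnknownColorBy("in_tissue_only requested but no in_tissue column")
        mask &= ds.col_annotations["in_tissue"].to_numpy().astype(bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelection(f"no plottable spots for sample {sample_id!r}")

    coords = ds.spatial_coords[idx]
    if coords.shape[1] < 2:
        raise EmptySelection("dataset has no 2-D spatial coordinates")

    image_row = None
    if spec.frame == "fullres":
        xy = coords[:, :2]
    elif spec.frame.startswith("image:"):
        image_id = spec.frame.split(":", 1)[1]
        rows = [
            r for r in ds.image_table if r.sample_id == sample_id and r.image_id == image_id
        ]
        if not rows:
            raise NoSuchImage(f"no image ({sample_id!r}, {image_id!r}) in the dataset")
        image_row = rows[0]
        xy = map_fullres_to_image(coords[:, :2], image_row.scale_factor)
    else:
        raise ValueError(f"frame must be 'fullres' or 'image:<id>', got {spec.frame!r}")

    values, color_scale = _resolve_color(ds, spec.color_by, idx)
    marker_size, size_source = _marker_size(ds, sample_id, image_row)

    fig, ax = plt.subplots(figsize=(5, 5))
    if image_row is not None:
        pixels = image_row.image.realize().pixels
        ax.imshow(pixels.squeeze(), origin="upper", zorder=0)
    if color_scale == "continuous":
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=marker_size, cmap="viridis", zorder=2)
        fig.colorbar(sc, ax=ax, label=spec.color_by)
    elif color_scale == "categorical":
        cats = pd.Categorical(values)
        cmap = plt.get_cmap("tab10")
        for code, cat in enumerate(cats.categories):
            sel = np.asarray(cats.codes) == code
            ax.scatter(
                xy[sel, 0], xy[sel, 1], color=cmap(code % 10), s=marker_size,
                label=str(cat), zorder=2,
            )
        ax.legend(title=spec.color_by, fontsize="small")
    else:
        ax.scatter(xy[:, 0], xy[:, 1], color="#3b6aa0", s=marker_size, zorder=2)
    _finish_axes(ax, sample_id)
    fig.savefig(spec.output)
    plt.close(fig)

    top = int(idx[np.argmin(xy[:, 1])])
    return {
        "n_points": int(idx.size),
        "bbox": _bbox(xy),
        "color_scale": color_scale,
        "marker_size": float(marker_size),
        "marker_size_source": size_source,
        "frame": spec.frame,
        "sample_id": sample_id,
        "topmost_barcode": str(ds.col_annotations["barcode_id"].iat[top]),
        "output": str(spec.output),
    }


def plot_molecules(dataset, feature_id, sample_id=None, output="molecules.png") -> dict:
    """One marker per detected molecule of one feature in one sample."""
    store = require_store(dataset)
    if feature_id not in set(store.feature_ids):
        raise UnknownFeature(f"feature {feature_id!r} not in the molecule store")
    sample_id = _default_sample(dataset, sample_id)
    obs = [k for k in store.obs_keys if k[0] == sample_id]
    recs = molecules_of(store, features=[feature_id], obs=obs)
    if len(recs) == 0:
        raise EmptySelection(f"feature {feature_id!r} has no molecules in {sample_id!r}")

    xy = recs[["x", "y"]].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xy[:, 0], xy[:, 1], s=3.0, color="#a03b52", alpha=0.8)
    ax.set_title(f"{feature_id} molecules — {sample_id}")
    _finish_axes(ax, sample_id)
    fig.savefig(output)
    plt.close(fig)
    return {
        "n_points": int(len(recs)),
        "bbox": _bbox(xy),
        "feature_id": feature_id,
        "sample_id": sample_id,
        "output": str(output),
    }


def plot_qc_counts(dataset, output="qc_counts.png") -> dict:
    """Histogram of per-observation library size (column sum of counts)."""
    counts = dataset.assay("counts")
    libsize = np.asarray(
        counts.sum(axis=0) if sp.issparse(counts) else np.asarray(counts).sum(axis=0)
    ).ravel()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(libsize, bins=min(30, max(1, len(np.unique(libsize)))), color="#3b6aa0")
    ax.set_xlabel("library size (total counts per observation)")
    ax.set_ylabel("observations")
    fig.tight_layout()
    fig.savefig(output)
    plt.close(fig)
    return {
        "n_obs": int(libsize.size),
        "min": float(libsize.min()),
        "max": float(libsize.max()),
        "library_sizes_sum": float(libsize.sum()),
        "output": str(output),
    }


# ---------------------------------------------------------------------- #
# helpers


def _default_sample(ds, sample_id):
    if sample_id is not None:
        if sample_id not in ds.sample_ids:
            raise EmptySelection(f"sample {sample_id!r} not in dataset {ds.sample_ids}")
        return sample_id
    return ds.sample_ids[0]


def _resolve_color(ds, color_by, idx):
    if color_by is None:
        return None, "none"
    if color_by in ds.col_annotations.columns:
        col = ds.col_annotations[color_by].iloc[idx]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            return col.to_numpy(dtype=float), "continuous"
        return col.astype(str).to_numpy(), "categorical"
    fids = ds.feature_ids
    if color_by in set(fids):
        row = fids.index(color_by)
        m = ds.assay("counts")
        vals = (m[row].toarray().ravel() if sp.issparse(m) else np.asarray(m)[row])[idx]
        return np.asarray(vals, dtype=float), "continuous"
    raise UnknownColorBy(
        f"{color_by!r} is neither a col_annotations column nor a feature_id"
    )


def _marker_size(ds, sample_id, image_row):
    sf = ds.metadata.get("scalefactors", {}).get(sample_id, {})
    diameter = sf.get("spot_diameter_fullres")
    if diameter is not None and image_row is not None:
        return float(diameter) * float(image_row.scale_factor), "spot_diameter_fullres"
    return FALLBACK_MARKER_SIZE, "fallback"


def _finish_axes(ax, sample_id):
    ax.set_aspect("equal")
    if not ax.yaxis_inverted():
        ax.invert_yaxis()  # y-down image convention: smallest pxl_row on top
    ax.set_xlabel("x (pixels)")
    ax.set_ylabel("y (pixels)")


def _bbox(xy):
    return [
        float(xy[:, 0].min()),
        float(xy[:, 0].max()),
        float(xy[:, 1].min()),
        float(xy[:, 1].max()),
    ]
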