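"""Sample-linked histology images with three storage modes.

A :class:`SpatialImage` is either fully realized in memory (``loaded``), a
path to a local file read on demand (``stored``), or a URL fetched on demand
(``remote``).  Constructing a stored/remote image performs **zero** reads of
the source; :meth:`SpatialImage.realize` loads it and memoizes the pixels so
repeated plotting never re-fetches.

Pixel layout is the image convention: row-major, origin at the top-left,
y increasing downward.  Spot-overlay plotting inherits this convention, which
is why image-frame plots flip the y axis.

Supported codecs: PNG, JPEG, TIFF.  Remote schemes: http, https and file
(``file://`` exists so the remote path is testable offline).
"""

from __future__ import annotations

import io
import urllib.parse
import urllib.request
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DuplicateImage, NoSuchImage, OrphanImage, UnreadableSource

_CODECS = {"PNG", "JPEG", "TIFF"}
_SCHEMES = {"http", "https", "file"}

WILDCARD = "*"


class SpatialImage:
    """One image in one of three storage modes.

    Parameters
    ----------
    pixels
        ``H x W x C`` uint8 array (C in {1, 3, 4}); sets mode ``loaded``.
    source
        Local path (mode ``stored``) or URL (mode ``remote``); exactly one of
        ``pixels``/``source`` must be given.
    """

    def __init__(self, pixels=None, source=None):
        if (pixels is None) == (source is None):
            raise ValueError("give exactly one of pixels= or source=")
        self._cache = None
        if pixels is not None:
            self.mode = "loaded"
            self.source = None
            self._cache = _check_pixels(np.asarray(pixels))
        else:
            self.source = str(source)
            scheme = urllib.parse.urlparse(self.source).scheme
            if scheme in _SCHEMES:
                self.mode = "remote"
            elif scheme in ("", None) or len(scheme) == 1:  # bare path / drive
                self.mode = "stored"
            else:
                raise UnreadableSource(
                    f"unsupported URL scheme {scheme!r} in {self.source!r}"
                )

    @property
    def pixels(self):
        """Pixel array if already in memory, else None (no read triggered)."""
        return self._cache

    def realize(self):
        """Return a mode=``loaded`` image, reading the source if necessary.

        The decoded pixels are memoized on this instance, so the read happens
        at most once; repeated calls are idempotent and byte-stable.  The
        returned image records where it came from in ``origin_mode``.
        """
        if self._cache is None:
            self._cache = _check_pixels(_decode(self._read_bytes(), self.source))
        out = SpatialImage(pixels=self._cache)
        out.origin_mode = self.mode
        out.source = self.source
        return out

    def _read_bytes(self):
        if self.mode == "stored":
            try:
                with open(self.source, "rb") as fh:
                    return fh.read()
            except OSError as exc:
                raise UnreadableSource(f"cannot read {self.source!r}: {exc}") from exc
        try:
            with urllib.request.urlopen(self.source) as fh:
                return fh.read()
        except (OSError, ValueError) as exc:
            raise UnreadableSource(f"cannot fetch {self.source!r}: {exc}") from exc

    @property
    def height(self):
        return self.realize().pixels.shape[0]

    @property
    def width(self):
        return self.realize().pixels.shape[1]

    def __repr__(self):
        src = "" if self.source is None else f" source={self.source!r}"
        px = "" if self._cache is None else f" {self._cache.shape}"
        return f"<SpatialImage mode={self.mode}{src}{px}>"


def _check_pixels(arr):
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3, 4):
        raise UnreadableSource(f"pixel array must be HxWxC, C in {{1,3,4}}; got {arr.shape}")
    if arr.dtype != np.uint8:
        raise UnreadableSource(f"pixel channels must be 8-bit, got dtype {arr.dtype}")
    return arr


def _decode(data: bytes, label) -> np.ndarray:
    try:
        img = Image.open(io.BytesIO(data))
        codec = img.format
        if codec not in _CODECS:
            raise UnreadableSource(
                f"{label!r}: codec {codec!r} not supported (PNG/JPEG/TIFF only)"
            )
        if img.mode not in ("L", "RGB", "RGBA"):
            img = img.convert("RGB")
        return np.asarray(img)
    except UnidentifiedImageError as exc:
        raise UnreadableSource(f"{label!r}: not a decodable image: {exc}") from exc


@dataclass(frozen=True)
class ImageRow:
    sample_id: str
    image_id: str
    scale_factor: float
    image: SpatialImage

    def __post_init__(self):
        if not (self.scale_factor > 0):
            raise ValueError(f"scale_factor must be > 0, got {self.scale_factor}")


@dataclass
class ImageTable:
    """Rows of (sample_id, image_id, scale_factor, SpatialImage).

    (sample_id, image_id) pairs are unique; rows keep insertion order.
    """

    rows: list = field(default_factory=list)

    def __post_init__(self):
        keys = [(r.sample_id, r.image_id) for r in self.rows]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DuplicateImage(f"duplicate (sample_id, image_id): {dupes}")

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def sample_ids(self):
        return [r.sample_id for r in self.rows]

    def with_row(self, row: ImageRow) -> "ImageTable":
        if any(r.sample_id == row.sample_id and r.image_id == row.image_id for r in self.rows):
            raise DuplicateImage(f"({row.sample_id!r}, {row.image_id!r}) already present")
        return ImageTable(self.rows + [row])

    def without(self, sample_id, image_id) -> "ImageTable":
        kept = [r for r in self.rows if not (r.sample_id == sample_id and r.image_id == image_id)]
        if len(kept) == len(self.rows):
            raise NoSuchImage(f"no image ({sample_id!r}, {image_id!r})")
        return ImageTable(kept)

    def restrict_to_samples(self, sample_ids) -> "ImageTable":
        keep = set(sample_ids)
        return ImageTable([r for r in self.rows if r.sample_id in keep])

    def renamed(self, mapping) -> "ImageTable":
        return ImageTable(
            [
                ImageRow(mapping.get(r.sample_id, r.sample_id), r.image_id, r.scale_factor, r.image)
                for r in self.rows
            ]
        )

    def select(self, sample_selector=WILDCARD, image_selector=WILDCARD):
        """Matching rows in table order; an empty match raises NoSuchImage."""
        out = [
            r
            for r in self.rows
            if (sample_selector == WILDCARD or r.sample_id == sample_selector)
            and (image_selector == WILDCARD or r.image_id == image_selector)
        ]
        if not out:
            raise NoSuchImage(
                f"no image matching sample={sample_selector!r}, image={image_selector!r}"
            )
        return out

    @staticmethod
    def concat(tables) -> "ImageTable":
        rows = [r for t in tables for r in t.rows]
        return ImageTable(rows)


def add_image(dataset, sample_id, image_id, source_or_pixels, scale_factor, load_now=False):
    """Append an image row to ``dataset`` and return the updated dataset.

    ``source_or_pixels`` is a pixel array (mode loaded), a path (stored) or a
    URL (remote).  Unless ``load_now`` is true, nothing is read from disk or
    network — laziness is part of the contract.
    """
    if sample_id not in set(dataset.col_annotations["sample_id"]):
        raise OrphanImage(f"sample_id {sample_id!r} not present in the dataset")
    if isinstance(source_or_pixels, SpatialImage):
        img = source_or_pixels
    elif isinstance(source_or_pixels, (str,)):
        img = SpatialImage(source=source_or_pixels)
    else:
        img = SpatialImage(pixels=source_or_pixels)
    if load_now:
        img = img.realize()
    try:
        row = ImageRow(sample_id, image_id, float(scale_factor), img)
    except ValueError as exc:
        raise ValueError(str(exc)) from None
    return dataset._replace(image_table=dataset.image_table.with_row(row))


def get_image(dataset, sample_selector=WILDCARD, image_selector=WILDCARD):
    """Image rows matching exact strings or the ``"*"`` wildcard."""
    return dataset.image_table.select(sample_selector, image_selector)


def remove_image(dataset, sample_id, image_id):
    return dataset._replace(image_table=dataset.image_table.without(sample_id, image_id))


def realize(image: SpatialImage) -> SpatialImage:
    """Functional spelling of :meth:`SpatialImage.realize`."""
    return image.realize()


def map_fullres_to_image(coords, scale_factor):
    """Map full-resolution pixel coordinates into a downsampled image's frame.

    Element-wise multiplication by ``scale_factor``; no rounding (callers
    round at draw time).  Dividing by the factor recovers the input to
    machine precision.
    """
    if not (scale_factor > 0):
        raise ValueError(f"scale_factor must be > 0, got {scale_factor}")
    return np.asarray(coords, dtype=float) * float(scale_factor)
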