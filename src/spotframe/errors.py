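"""Exception hierarchy for spotframe.

Every error raised by the package derives from :class:`SpotFrameError` so
callers can catch the whole family with one clause.  Validation of a dataset
collects *all* findings before raising: if the findings are homogeneous the
specific class is raised (so ``pytest.raises(DimensionMismatch)`` works), and
a mixed bag raises :class:`ValidationError` carrying the full list.
"""

from __future__ import annotations


class SpotFrameError(Exception):
    """Base class for all spotframe errors."""


class ValidationError(SpotFrameError):
    """Raised when dataset validation finds problems of more than one kind.

    ``findings`` is a list of ``(error_class, message)`` pairs covering every
    problem detected, not just the first.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        msgs = "; ".join(m for _, m in self.findings)
        super().__init__(f"{len(self.findings)} validation problem(s): {msgs}")


class DimensionMismatch(SpotFrameError):
    """A component's shape conflicts with the dataset's (n_features, n_obs)."""


class DuplicateKey(SpotFrameError):
    """Repeated feature_id or repeated (sample_id, barcode_id) pair."""


class OrphanImage(SpotFrameError):
    """An image row references a sample_id absent from the observations."""


class UnknownComponent(SpotFrameError):
    """Component name not in the container's vocabulary."""


class UnknownEntry(SpotFrameError):
    """Named assay or reduced-dimension entry not present."""


class SelectorOutOfRange(SpotFrameError):
    """Integer or boolean selector does not fit the axis."""


class UnknownID(SpotFrameError):
    """String selector names a feature/observation that does not exist."""


class FeatureMismatch(SpotFrameError):
    """Datasets being combined do not share an identical feature sequence."""


class SampleClash(SpotFrameError):
    """Duplicate sample_id across datasets under the require_unique policy."""


class UnknownFeature(SpotFrameError):
    """Molecule record references a feature absent from the dataset."""


class UnknownObservation(SpotFrameError):
    """Molecule record references an observation absent from the dataset."""


class MalformedRecord(SpotFrameError):
    """Molecule record with a non-finite coordinate."""


class NoMoleculeStore(SpotFrameError):
    """Operation requires an attached molecule store and none is present."""


class DuplicateImage(SpotFrameError):
    """(sample_id, image_id) already present in the image table."""


class UnreadableSource(SpotFrameError):
    """Image source missing, unreachable or not a supported codec."""


class NoSuchImage(SpotFrameError):
    """Image selector matched nothing (empty matches are errors, not [])."""


class MissingFile(SpotFrameError):
    """A required Space Ranger bundle file is absent; names which."""


class DialectError(SpotFrameError):
    """Tissue-positions file has a malformed header or column count."""


class BarcodeJoinError(SpotFrameError):
    """Zero barcodes shared between matrix and positions file."""


class NotVisiumShaped(SpotFrameError):
    """Dataset lacks the columns/axes a Visium bundle writer requires."""


class UnknownColorBy(SpotFrameError):
    """plot color_by resolves to neither an annotation column nor a feature."""


class EmptySelection(SpotFrameError):
    """Plot selection contains nothing to draw."""


class ArgumentError(SpotFrameError):
    """Invalid argument to a fixture generator."""
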