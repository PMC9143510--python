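"""Exception hierarchy.

Everything user-facing raises a subclass of :class:`PhenodeepError` so the
command-line layer can turn any pipeline failure into a clean non-zero exit.
"""


class PhenodeepError(Exception):
    """Base class for all errors raised by this package."""


class LineageParseError(PhenodeepError):
    """A taxonomic lineage string could not be parsed."""


class ProfileParseError(PhenodeepError):
    """An abundance-profile file is malformed."""


class MetadataError(PhenodeepError):
    """Sample metadata is malformed or inconsistent."""


class AlignmentError(PhenodeepError):
    """Abundance table and metadata could not be reconciled."""


class PreprocessError(PhenodeepError):
    """A preprocessing step received input it cannot handle."""


class SplitError(PreprocessError):
    """A stratified split cannot be formed (class too small, bad fractions)."""


class DivergedError(PhenodeepError):
    """Training produced a non-finite loss."""


class SearchError(PhenodeepError):
    """Hyperparameter search failed (e.g. every trial diverged)."""


class ModelArchiveError(PhenodeepError):
    """A model archive is missing, corrupted, or from an unknown format version."""
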