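"""Exception hierarchy for nirdx.

All errors derive from :class:`NirdxError` so callers can catch the package's
failures with a single except clause; most also derive from the closest
builtin (ValueError / RuntimeError) so generic handling keeps working.
"""


class NirdxError(Exception):
    """Base class for all nirdx errors."""


class FormatError(NirdxError, ValueError):
    """Malformed input file or mismatched spectra/metadata tables."""


class ParseError(NirdxError, ValueError):
    """Non-numeric or otherwise unparseable cell content."""


class GridError(NirdxError, ValueError):
    """Invalid wavenumber grid (duplicates, out of bounds, non-monotone)."""


class ShapeError(NirdxError, ValueError):
    """Array dimensions do not line up."""


class EmptyIntervalError(NirdxError, ValueError):
    """A requested wavenumber interval contains no grid points."""


class EmptySelectionError(NirdxError, ValueError):
    """A label/filter selection matched no spectra."""


class ParameterError(NirdxError, ValueError):
    """Invalid operator or model hyperparameter."""


class DegenerateSpectrumError(NirdxError, ValueError):
    """A per-spectrum transform hit a degenerate input (e.g. zero variance)."""


class DegenerateFitError(NirdxError, ValueError):
    """A least-squares fit inside an operator collapsed (e.g. MSC slope ~ 0)."""


class DegenerateDataError(NirdxError, ValueError):
    """A whole-matrix operation received degenerate data (e.g. all zeros)."""


class NAModelError(NirdxError, RuntimeError):
    """Use of a PCA model flagged invalid (variance threshold unreachable)."""


class StateError(NirdxError, RuntimeError):
    """Operation requires a fitted/trained model that is not available."""


class DataError(NirdxError, ValueError):
    """Empty or inconsistent data passed to a model or aggregator."""


class LabelError(NirdxError, ValueError):
    """Unknown class label or malformed one-hot row."""


class NoModelError(NirdxError, RuntimeError):
    """Model selection found no usable (non-NA) candidate."""
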