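"""Exception hierarchy shared by all spottype modules.

The CLI maps these onto exit codes: :class:`SpotTypeError` subclasses other
than :class:`NoMarkerGenesError` exit with 2 (lookup/validation/format
problems), :class:`NoMarkerGenesError` exits with 3 (the targeted-panel
failure mode where no marker gene is detected in the data), anything else
exits with 1.
"""


class SpotTypeError(Exception):
    """Base class for all errors raised by spottype."""


class FormatError(SpotTypeError):
    """A file does not conform to the expected dialect (missing columns,

    dimension mismatches between an MTX header and its sidecar TSVs, ...).
    """


class ValidationError(SpotTypeError):
    """Input data violates a documented invariant (duplicate keys, a gene

    listed as both positive and negative marker of one cell type, ...).
    """


class TissueLookupError(SpotTypeError):
    """The requested tissue is not present in the marker database."""


class NoMarkerGenesError(SpotTypeError):
    """None of the marker genes are detected in the expression matrix.

    This is the hard failure observed on targeted panels whose probe set
    does not overlap the marker database.
    """
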