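"""Exception hierarchy for imfuse."""


class ImfuseError(Exception):
    """Base class for all imfuse errors."""


class DataFormatError(ImfuseError):
    """A file does not follow the expected dialect (missing header,
    missing ``@data`` section, constant label column, ...)."""


class ParseError(DataFormatError):
    """A feature cell could not be parsed as a finite real."""


class UnsupportedMulticlassError(ImfuseError):
    """More than two distinct class labels were found; only binary
    problems are supported."""


class InsufficientSamplesError(ImfuseError):
    """A class is too small for the requested operation (stratified
    folds, neighbor counts, SMOTE seeds, target neighbors...)."""


class UndefinedAUCError(ImfuseError):
    """AUC requested on a single-class label vector."""


class DivergenceError(ImfuseError):
    """The metric-learning optimizer produced a non-finite loss."""
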