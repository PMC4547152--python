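"""Exception hierarchy shared by all histograph modules.

The CLI maps these onto exit codes: invalid input -> 2, invalid
parameters -> 3.
"""


class HistographError(Exception):
    """Base class for all errors raised by histograph."""


class InvalidInputError(HistographError):
    """The data handed to an operation violates its preconditions."""


class InvalidParameterError(HistographError):
    """A tuning parameter is outside its documented range."""


class EmptyTrainingSetError(InvalidInputError):
    """No descriptors were available to train a codebook from."""


class AnnotationFormatError(InvalidInputError):
    """An annotation file could not be parsed."""


class DuplicateIdError(AnnotationFormatError):
    """An annotation file contains the same image id twice."""
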