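"""Exception hierarchy shared across the pipeline stages."""


class XlripError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(XlripError):
    """A required column or field is missing from an input table."""


class RecordError(XlripError):
    """A single row/record is malformed; the message carries its index."""


class ConfigError(XlripError):
    """A configuration value is missing, unparsable, or out of range."""


class DataError(XlripError):
    """Input data violate a content contract (negative counts, duplicates...)."""


class FormatError(XlripError):
    """A structure or table file could not be parsed at all."""


class TrainingError(XlripError):
    """Classifier training is impossible with the records provided."""
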