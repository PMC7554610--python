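"""Exception hierarchy shared by all vrano modules."""


class VranoError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VranoError, ValueError):
    """An argument is outside its physical or logical domain."""


class ModelValidityError(VranoError, ValueError):
    """A radiobiological model was evaluated outside its validity range."""


class MissingBaselineError(VranoError, ValueError):
    """A lesion trajectory has no pre-treatment baseline measurement."""


class DataOrderError(VranoError, ValueError):
    """Measurements are not strictly ordered in time (or timestamps tie)."""


class IncompleteEventError(VranoError, ValueError):
    """A clinical event lacks a required field (e.g. resection without histology)."""


class IncompleteDataError(VranoError, ValueError):
    """A required measurement field (e.g. diameter) is absent."""


class InvalidReferenceError(VranoError, ValueError):
    """A progression test was given a non-positive reference measurement."""


class InconsistentRecordError(VranoError, ValueError):
    """Event and imaging dates of a lesion record contradict each other."""


class SchemaError(VranoError, ValueError):
    """A tabular input is missing a required column."""
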