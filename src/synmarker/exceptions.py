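"""Exception hierarchy for synmarker."""


class SynmarkerError(Exception):
    """Base class for all synmarker errors."""


class FormatError(SynmarkerError):
    """A file could not be parsed in the expected tabular dialect."""


class LabelError(SynmarkerError):
    """Sample labels are missing or inconsistent with the expression matrix."""


class DegenerateClassError(SynmarkerError):
    """A class has too few samples for variance estimation (< 2)."""


class DegenerateNetworkError(SynmarkerError):
    """The induced network is empty or otherwise unusable."""


class DegenerateSimilarityError(SynmarkerError):
    """The similarity structure has no finite entries."""


class MissingGeneError(SynmarkerError):
    """A marker member gene is absent from the dataset it is evaluated on."""
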