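"""Exception hierarchy for the latentmol pipeline."""


class LatentMolError(Exception):
    """Base class for all latentmol errors."""


class ParseError(LatentMolError):
    """A SMILES string could not be parsed into a molecule."""


class EncodeError(LatentMolError):
    """A molecule cannot be expressed in the restricted SELFIES grammar."""


class DecodeError(LatentMolError):
    """A SELFIES string could not be decoded (malformed token stream)."""


class VocabularyError(LatentMolError):
    """A token or character is absent from the sequence alphabet."""


class CapacityError(LatentMolError):
    """The corpus has more distinct tokens than available mono-characters."""


class SequenceLengthError(LatentMolError):
    """A molecular sequence exceeds the model's padded length budget."""


class EmptyCorpusError(LatentMolError):
    """Filtering or preparation produced an empty corpus."""


class ConfigurationError(LatentMolError):
    """Inconsistent configuration (e.g. alphabet mismatch between datasets)."""


class BackendError(LatentMolError):
    """A docking backend is unavailable or failed."""
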