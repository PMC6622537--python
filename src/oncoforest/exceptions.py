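"""Exception hierarchy for oncoforest.

All package errors derive from :class:`OncoforestError` so callers can catch
one base class at CLI boundaries.
"""


class OncoforestError(Exception):
    """Base class for all oncoforest errors."""


class FormatError(OncoforestError):
    """A file could not be parsed into the expected tabular schema."""


class ValidationError(OncoforestError):
    """A table violates a domain invariant (duplicates, out-of-domain values...)."""


class ReferentialIntegrityError(OncoforestError):
    """Tables reference drug or cell-line identifiers unknown to each other."""


class ConfigurationError(OncoforestError):
    """Infeasible or inconsistent configuration of a generator or experiment."""


class ChemistryError(OncoforestError):
    """A SMILES string could not be parsed or featurized."""


class DegenerateLabelsError(OncoforestError):
    """Training labels contain a single class where two are required."""
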