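"""Exception hierarchy for the oenotype pipeline."""


class OenotypeError(Exception):
    """Base class for all errors raised by this package."""


class UnsupportedPhenotype(OenotypeError):
    """An assay outcome has no code in the ordinal coding scheme."""


class IncompleteAssay(OenotypeError):
    """An assay time/dose series is missing required observations."""


class EmptyDataset(OenotypeError):
    """An operation that requires data received none."""


class EmptyPattern(OenotypeError):
    """A fingerprint band pattern with no bands."""


class NotEnoughItems(OenotypeError):
    """Fewer items than the operation can meaningfully process."""


class InvalidSheet(OenotypeError):
    """A free-sorting sheet does not cover exactly the expected wine set."""


class NonMonotoneProfile(UserWarning):
    """Growth observed at a high dose but not at a lower one (plate artifact)."""
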