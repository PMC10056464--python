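"""Exception hierarchy for pvdose.

All package-specific failures derive from :class:`PvdoseError` so callers
(and the CLI) can distinguish user/data errors from genuine bugs.
"""


class PvdoseError(Exception):
    """Base class for all pvdose errors."""


class ParseError(PvdoseError):
    """A count table could not be parsed; carries row/column context."""


class DatasetValidationError(PvdoseError):
    """A dataset violates structural invariants (negative counts, duplicates...).

    ``findings`` holds every violation found, not just the first.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__("; ".join(str(f) for f in self.findings))


class ExcludedTermError(PvdoseError):
    """A preferred term carries an exclusion marker (e.g. 'intentional')
    and must not be counted in a medication-error analysis."""


class TaxonomyConflictError(PvdoseError):
    """Two taxonomy entries assign the same preferred term to different
    dosing-error categories."""


class DegenerateInputError(PvdoseError):
    """An operation received an input on which its statistic is undefined
    (zero denominator, constant vector, zero cell under the reject policy)."""


class MissingDrugError(PvdoseError):
    """A requested target drug is absent from the dataset."""


class ConfigError(PvdoseError):
    """A simulation or run configuration violates its invariants."""
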