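"""Exception hierarchy.

Every error raised by the library derives from :class:`AmpholyteError`, so
callers (and the CLI) can catch one type.  Prediction-level failures that a
batch run must tolerate — a peptide without an isoelectric point, a sequence a
method does not apply to — derive from :class:`PredictionFailure` and carry a
short machine-readable ``reason`` used in prediction records.
"""

from __future__ import annotations


class AmpholyteError(Exception):
    """Base class for all library errors."""


class ValidationError(AmpholyteError, ValueError):
    """An input value violates a documented contract."""


class SequenceError(ValidationError):
    """A residue string or modification annotation is malformed."""


class UnknownNameError(AmpholyteError, KeyError):
    """A registry lookup failed; the message lists the registered names."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message flat
        return self.args[0] if self.args else ""


class RegistryConflictError(AmpholyteError):
    """Attempt to register a name that already exists without overwrite."""


class DataFileError(AmpholyteError):
    """A bundled or user-supplied data file is malformed."""


class SchemaError(ValidationError):
    """A tabular dataset is missing a required column."""


class PredictionFailure(AmpholyteError):
    """Base for per-sequence failures that batch runs record, not raise."""

    reason: str = "prediction_failure"


class NoIsoelectricPointError(PredictionFailure):
    """Net charge has the same sign over the whole pH domain (or no groups).

    Happens for single-polarity group lists, e.g. an N-terminally acetylated
    peptide whose remaining groups are all acids.
    """

    reason = "no_isoelectric_point"


class NotApplicableError(PredictionFailure):
    """The method's applicability precondition fails for this sequence.

    Distinct from a numerical failure: e.g. the Branca scheme is only defined
    for peptides with a K/R C-terminus (tryptic peptides).
    """

    reason = "not_applicable"


class InvalidSequenceFailure(PredictionFailure):
    reason = "invalid_sequence"


class ConvergenceError(AmpholyteError):
    """An iterative scheme failed to converge; message reports last estimates."""


class DataSizeError(ValidationError):
    """Too few records to train a learning method reliably."""


class FeatureSpecError(AmpholyteError):
    """A model's feature specification does not match the current environment."""
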