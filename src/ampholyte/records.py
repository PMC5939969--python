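"""Shared record types: the universal dataset row and prediction row."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .modifications import ModifiedSequence

#: failure reasons a PredictionRecord may carry
FAILURE_REASONS = ("no_isoelectric_point", "not_applicable", "invalid_sequence")


@dataclass(frozen=True)
class DatasetRecord:
    """One benchmark observation: a sequence with an experimental pI."""

    id: str
    sequence: ModifiedSequence
    experimental_pi: float
    fraction: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < float(self.experimental_pi) < 14.0:
            raise ValidationError(
                f"record {self.id!r}: experimental pI {self.experimental_pi} "
                "outside (0, 14)"
            )


@dataclass(frozen=True)
class PredictionRecord:
    """One per-sequence method output: a pI, or an annotated failure.

    Exactly one of ``predicted_pi`` / ``failure_reason`` is set.
    """

    id: str
    method: str
    pka_set_or_variant: str
    predicted_pi: float | None = None
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.predicted_pi is None) == (self.failure_reason is None):
            raise ValidationError(
                f"record {self.id!r}: exactly one of predicted_pi / "
                "failure_reason must be present"
            )
        if self.failure_reason is not None and self.failure_reason not in FAILURE_REASONS:
            raise ValidationError(
                f"record {self.id!r}: unknown failure reason {self.failure_reason!r}"
            )

    @property
    def ok(self) -> bool:
        return self.predicted_pi is not None
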