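"""Audit-trail events emitted by every curation stage.

Every record or per-gene entry that is removed, flagged, or rejected
anywhere in the pipeline produces exactly one :class:`CurationEvent`, so
that the union of retained entries and event subjects always partitions
the input.  Reason codes form a closed vocabulary; downstream reporting
and the synthetic-fixture truth tables key on these strings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable


class Reason(str, enum.Enum):
    """Closed set of removal/flag reasons."""

    NOT_MITO = "NOT_MITO"
    NOT_METAZOA = "NOT_METAZOA"
    TAXID_UNRESOLVED = "TAXID_UNRESOLVED"
    BAD_ALPHABET = "BAD_ALPHABET"
    AMBIGUOUS_GENE = "AMBIGUOUS_GENE"
    UNKNOWN_GENE = "UNKNOWN_GENE"
    EXCISION_ERROR = "EXCISION_ERROR"
    NO_SPECIES_RANK = "NO_SPECIES_RANK"
    FORBIDDEN_TOKEN = "FORBIDDEN_TOKEN"
    BLACKLISTED_ID = "BLACKLISTED_ID"
    LENGTH_OUT_OF_RANGE = "LENGTH_OUT_OF_RANGE"
    MISLABEL_FLAGGED = "MISLABEL_FLAGGED"
    MISLABEL_REMOVED = "MISLABEL_REMOVED"
    PARSE_ERROR = "PARSE_ERROR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CurationEvent:
    """One audit entry: *subject* was acted on at *stage* for *reason*."""

    subject: str
    stage: str
    reason: Reason
    detail: str = ""

    def as_row(self) -> tuple[str, str, str, str]:
        return (self.subject, self.stage, self.reason.value, self.detail)


def events_to_tsv(events: Iterable[CurationEvent]) -> str:
    """Serialise events as a 4-column TSV with a header line."""
    lines = ["subject\tstage\treason\tdetail"]
    for ev in events:
        lines.append("\t".join(ev.as_row()))
    return "\n".join(lines) + "\n"
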