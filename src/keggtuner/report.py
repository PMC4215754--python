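"""Modification tracking: records and log files.

Every mutation applied to a pathway — by a correction or by tuning —
emits exactly one :class:`Record`; reports aggregate records and write
them to machine-parsable log files (one line per record: ISO timestamp,
kind, tab-separated ``key=value`` detail fields).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timezone


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class Record:
    kind: str
    details: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=_now)

    def to_log_line(self) -> str:
        fields = "\t".join(f"{k}={self.details[k]}" for k in self.details)
        return f"{self.timestamp}\t{self.kind}" + ("\t" + fields if fields else "")


@dataclass
class Report:
    """Ordered record list with per-kind tallies."""

    records: list = field(default_factory=list)

    def add(self, kind: str, **details) -> Record:
        rec = Record(kind=kind, details=details)
        self.records.append(rec)
        return rec

    def extend(self, other: "Report") -> None:
        self.records.extend(other.records)

    @property
    def counts(self) -> dict:
        return dict(Counter(rec.kind for rec in self.records))

    def count(self, kind: str) -> int:
        return self.counts.get(kind, 0)

    def __len__(self) -> int:
        return len(self.records)

    def to_log_text(self) -> str:
        return "".join(rec.to_log_line() + "\n" for rec in self.records)

    def write_log(self, path, mode: str = "a") -> None:
        with open(path, mode, encoding="utf-8") as fh:
            fh.write(self.to_log_text())


class CorrectionReport(Report):
    """Report of inconsistency corrections applied to a pathway."""


class TuningReport(Report):
    """Report of context-specific tuning steps applied to a pathway."""
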