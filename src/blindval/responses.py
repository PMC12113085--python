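"""Validator judgments: label scheme, append-only log, and the review loop.

The validator sees one blinded mask at a time and assigns one label from
a configurable scheme.  The shipped default is the four-category scheme
used in dense-tissue validation — correct / oversegmented /
undersegmented / incorrect — with ``correct`` alone forming the "agree"
subset; every analysis that needs a binary view collapses labels to
agree vs disagree through the scheme.

Responses carry two timestamps: when the item was displayed (shown_at)
and when the label was committed (answered_at).  Both are stored as
timezone-aware UTC datetimes so that session-gap analysis is unambiguous.
Free-text comments are stored verbatim and never enter any statistic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable

from .errors import BlindingError, ResponseError

__all__ = [
    "LabelScheme",
    "DEFAULT_SCHEME",
    "ValidationResponse",
    "ResponseLog",
    "collapse_binary",
    "CompletenessReport",
    "completeness_check",
    "review_loop",
]


@dataclass(frozen=True)
class LabelScheme:
    """Ordered label categories and the designated "agree" subset."""

    categories: tuple[str, ...]
    agree: frozenset[str]

    def __post_init__(self):
        if len(set(self.categories)) != len(self.categories):
            raise ResponseError("label categories must be unique")
        agree = frozenset(self.agree)
        if not agree or not agree < set(self.categories):
            raise ResponseError(
                "agree subset must be a nonempty proper subset of the categories"
            )
        object.__setattr__(self, "agree", agree)

    @property
    def disagree(self) -> frozenset[str]:
        return frozenset(self.categories) - self.agree

    def to_dict(self) -> dict:
        return {"categories": list(self.categories), "agree": sorted(self.agree)}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelScheme":
        return cls(categories=tuple(d["categories"]), agree=frozenset(d["agree"]))


DEFAULT_SCHEME = LabelScheme(
    categories=("correct", "oversegmented", "undersegmented", "incorrect"),
    agree=frozenset({"correct"}),
)


def collapse_binary(label: str, scheme: LabelScheme = DEFAULT_SCHEME) -> str:
    """Collapse a label to ``"agree"`` or ``"disagree"`` under the scheme."""
    if label not in scheme.categories:
        raise ResponseError(f"unknown label {label!r} for scheme {scheme.categories}")
    return "agree" if label in scheme.agree else "disagree"


_TS_FMT = "%Y-%m-%dT%H:%M:%S%z"


def _parse_ts(text: str) -> datetime:
    dt = datetime.fromisoformat(text)
    if dt.tzinfo is None:
        raise ResponseError(f"timestamp {text!r} lacks a UTC offset")
    return dt.astimezone(timezone.utc)


@dataclass(frozen=True)
class ValidationResponse:
    """One validator judgment of one blinded presentation."""

    presentation_id: str
    label: str
    comment: str = ""
    shown_at: datetime = field(default_factory=lambda: datetime.now(timezone.utc))
    answered_at: datetime = field(default_factory=lambda: datetime.now(timezone.utc))

    def __post_init__(self):
        for name in ("shown_at", "answered_at"):
            ts = getattr(self, name)
            if ts.tzinfo is None:
                raise ResponseError(f"{name} must be timezone-aware")
            object.__setattr__(self, name, ts.astimezone(timezone.utc))
        if self.answered_at < self.shown_at:
            raise ResponseError(
                f"answered_at precedes shown_at for {self.presentation_id}"
            )


_CSV_HEADER = ["presentation_id", "label", "comment", "shown_at", "answered_at"]


class ResponseLog:
    """Append-only collection of responses under one label scheme.

    When constructed with a ``path`` the log persists each appended
    response immediately (header on first write, one flushed CSV row per
    response), so a crash loses at most the in-flight item.
    """

    def __init__(self, scheme: LabelScheme = DEFAULT_SCHEME, path: str | Path | None = None):
        self.scheme = scheme
        self._responses: list[ValidationResponse] = []
        self._ids: set[str] = set()
        self._path = Path(path) if path is not None else None
        if self._path is not None and not self._path.exists():
            with open(self._path, "w", newline="") as fh:
                csv.writer(fh).writerow(_CSV_HEADER)

    def __len__(self) -> int:
        return len(self._responses)

    def __iter__(self):
        return iter(self._responses)

    @property
    def responses(self) -> tuple[ValidationResponse, ...]:
        return tuple(self._responses)

    def append(self, response: ValidationResponse) -> "ResponseLog":
        if response.presentation_id in self._ids:
            raise ResponseError(
                f"presentation {response.presentation_id} already answered"
            )
        if response.label not in self.scheme.categories:
            raise ResponseError(
                f"unknown label {response.label!r}; scheme allows {self.scheme.categories}"
            )
        self._responses.append(response)
        self._ids.add(response.presentation_id)
        if self._path is not None:
            with open(self._path, "a", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(self._row(response))
                fh.flush()
        return self

    @staticmethod
    def _row(r: ValidationResponse) -> list[str]:
        return [r.presentation_id, r.label, r.comment,
                r.shown_at.strftime(_TS_FMT), r.answered_at.strftime(_TS_FMT)]

    # ------------------------------------------------------------------
    # serialization (CSV with RFC 4180 quoting; JSONL mirror)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_CSV_HEADER)
            for r in self._responses:
                w.writerow(self._row(r))

    @classmethod
    def from_csv(cls, path: str | Path, scheme: LabelScheme = DEFAULT_SCHEME) -> "ResponseLog":
        log = cls(scheme=scheme)
        with open(path, "r", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != _CSV_HEADER:
                raise ResponseError(
                    f"response CSV header must be {_CSV_HEADER}, got {reader.fieldnames}"
                )
            for row in reader:
                log.append(ValidationResponse(
                    presentation_id=row["presentation_id"],
                    label=row["label"],
                    comment=row["comment"],
                    shown_at=_parse_ts(row["shown_at"]),
                    answered_at=_parse_ts(row["answered_at"]),
                ))
        return log

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self._responses:
                fh.write(json.dumps({
                    "presentation_id": r.presentation_id,
                    "label": r.label,
                    "comment": r.comment,
                    "shown_at": r.shown_at.strftime(_TS_FMT),
                    "answered_at": r.answered_at.strftime(_TS_FMT),
                }) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path, scheme: LabelScheme = DEFAULT_SCHEME) -> "ResponseLog":
        log = cls(scheme=scheme)
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                log.append(ValidationResponse(
                    presentation_id=d["presentation_id"],
                    label=d["label"],
                    comment=d.get("comment", ""),
                    shown_at=_parse_ts(d["shown_at"]),
                    answered_at=_parse_ts(d["answered_at"]),
                ))
        return log


@dataclass(frozen=True)
class CompletenessReport:
    """Which planned presentations lack a response, and vice versa."""

    missing: tuple[str, ...]  # in plan, no response
    extra: tuple[str, ...]    # responded, not in plan

    @property
    def complete(self) -> bool:
        return not self.missing and not self.extra


def completeness_check(log: ResponseLog, plan) -> CompletenessReport:
    """Report-only reconciliation of a response log against its plan."""
    plan_ids = list(plan.presentation_ids)
    answered = {r.presentation_id for r in log}
    missing = tuple(pid for pid in plan_ids if pid not in answered)
    extra = tuple(r.presentation_id for r in log if r.presentation_id not in set(plan_ids))
    return CompletenessReport(missing=missing, extra=extra)


def review_loop(
    plan,
    mask_provider: Callable[[str], object],
    scheme: LabelScheme = DEFAULT_SCHEME,
    driver: Callable[[str, object], tuple[str, str] | None] | None = None,
    clock: Callable[[], datetime] | None = None,
    log: ResponseLog | None = None,
) -> ResponseLog:
    """Drive the blinded review: one item at a time, in schedule order.

    ``mask_provider`` maps a presentation id to whatever the driver should
    display (a mask, an image path, ...); it must not expose provenance.
    ``driver`` is called with (presentation_id, displayed object) and
    returns (label, comment), or None to quit mid-run (the partial log is
    returned and will fail completeness, not integrity).  An invalid
    label leaves the item pending: the driver is asked again.

    The default driver reads labels from stdin, which is what the CLI
    ``review`` stage uses.
    """
    if driver is None:
        driver = _stdin_driver(scheme)
    if clock is None:
        clock = lambda: datetime.now(timezone.utc)
    if log is None:
        log = ResponseLog(scheme=scheme)
    answered = {r.presentation_id for r in log}
    for item in plan.items:
        pid = item.presentation_id
        if pid in answered:
            continue
        display = mask_provider(pid)
        if isinstance(display, dict) and (
            {"image_id", "source_id", "replicate"} & set(display)
        ):
            raise BlindingError("mask provider leaked provenance fields to the review loop")
        shown_at = clock()
        while True:
            answer = driver(pid, display)
            if answer is None:
                return log  # validator quit; item stays pending
            label, comment = answer
            if label in scheme.categories:
                break
            # unknown label: the item stays pending and is asked again
        log.append(ValidationResponse(
            presentation_id=pid, label=label, comment=comment,
            shown_at=shown_at, answered_at=clock(),
        ))
    return log


def _stdin_driver(scheme: LabelScheme):
    def driver(pid: str, display):
        print(f"\n[{pid[:8]}…] mask: {display}")
        print(f"labels: {', '.join(scheme.categories)} (or 'quit')")
        label = input("label> ").strip()
        if label == "quit":
            return None
        comment = input("comment (optional)> ").strip()
        return label, comment
    return driver
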