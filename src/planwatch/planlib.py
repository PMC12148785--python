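"""Community Plan Library: CSV append / load / similarity filtering.

Dialect: UTF-8, comma-separated, "." decimal, ISO-8601 timestamps. The
first line is a ``#schema=1`` version marker, the second the header:
fixed prefix columns followed by one column per constraint metric (the
metric-grammar string, prefixed by its role). Patient identifiers are
stored only as salted hashes.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import os
import time
from dataclasses import dataclass, field
from enum import Enum

from .exceptions import ValidationError, VersioningError

log = logging.getLogger(__name__)

SCHEMA_LINE = "#schema=1"

PREFIX_COLUMNS = (
    "timestamp", "user", "patient_key", "plan_id", "protocol", "laterality",
    "boost", "nodes", "breast_mod", "technique", "tech_mods", "bolus",
    "mu_sum", "bw_score",
)


class Privilege(str, Enum):
    OWN_ONLY = "OWN_ONLY"
    ALL = "ALL"


def pseudonymize(patient_id: str, salt: str = "planwatch") -> str:
    """Salted short hash; raw identifiers never reach the library file."""
    return hashlib.sha256(f"{salt}:{patient_id}".encode()).hexdigest()[:16]


@dataclass
class PlanRecord:
    timestamp: str
    user: str
    patient_key: str
    plan_id: str
    protocol: str
    laterality: str
    has_boost: bool
    has_nodes: bool
    breast_modifier: str
    technique: str
    technique_modifiers: frozenset[str]
    bolus: str
    mu_sum: float
    bw_score: int | None
    metrics: dict[str, float | None] = field(default_factory=dict)

    def metric_columns(self) -> list[str]:
        return list(self.metrics)

    def to_row(self) -> list[str]:
        def fmt(v) -> str:
            if v is None:
                return ""
            if isinstance(v, bool):
                return "1" if v else "0"
            if isinstance(v, float):
                return f"{v:g}"
            return str(v)

        row = [
            self.timestamp, self.user, self.patient_key, self.plan_id,
            self.protocol, self.laterality,
            fmt(self.has_boost), fmt(self.has_nodes),
            self.breast_modifier, self.technique,
            "+".join(sorted(self.technique_modifiers)), self.bolus,
            fmt(float(self.mu_sum)), fmt(self.bw_score),
        ]
        row += [fmt(self.metrics[k]) for k in self.metrics]
        return row


def _header_for(record: PlanRecord) -> list[str]:
    return list(PREFIX_COLUMNS) + record.metric_columns()


def _parse_row(header: list[str], row: list[str]) -> PlanRecord:
    if len(row) != len(header):
        raise ValidationError(f"row has {len(row)} fields, header has {len(header)}")
    d = dict(zip(header, row))
    metrics = {
        k: (float(d[k]) if d[k] != "" else None)
        for k in header[len(PREFIX_COLUMNS):]
    }
    return PlanRecord(
        timestamp=d["timestamp"],
        user=d["user"],
        patient_key=d["patient_key"],
        plan_id=d["plan_id"],
        protocol=d["protocol"],
        laterality=d["laterality"],
        has_boost=d["boost"] == "1",
        has_nodes=d["nodes"] == "1",
        breast_modifier=d["breast_mod"],
        technique=d["technique"],
        technique_modifiers=frozenset(t for t in d["tech_mods"].split("+") if t),
        bolus=d["bolus"],
        mu_sum=float(d["mu_sum"]) if d["mu_sum"] else 0.0,
        bw_score=int(float(d["bw_score"])) if d["bw_score"] else None,
        metrics=metrics,
    )


def _read_header(path: str) -> list[str]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        first = fh.readline().strip()
        if first != SCHEMA_LINE:
            raise VersioningError(
                f"{path}: expected first line {SCHEMA_LINE!r}, found {first!r}; "
                "migrate the file or start a new library"
            )
        reader = csv.reader(fh)
        try:
            return next(reader)
        except StopIteration:
            raise VersioningError(f"{path}: schema line without header row") from None


def append_record(
    library_path: str, record: PlanRecord, retries: int = 3
) -> tuple[int, int]:
    """Append *record*; returns (records by this user, total records).

    Creates the file (schema line + header) if absent. A header mismatch
    raises :class:`VersioningError` — libraries are per-protocol files and
    all writers must agree on the constraint set.
    """
    header = _header_for(record)
    if os.path.exists(library_path):
        existing = _read_header(library_path)
        if existing != header:
            extra = set(header) - set(existing)
            missing = set(existing) - set(header)
            raise VersioningError(
                f"{library_path}: header mismatch (record adds {sorted(extra)}, "
                f"lacks {sorted(missing)}); export to a new library file or "
                "migrate the old one"
            )
        mode = "a"
    else:
        mode = "w"

    last_error: OSError | None = None
    for attempt in range(retries):
        try:
            with open(library_path, mode, encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh)
                if mode == "w":
                    fh.write(SCHEMA_LINE + "\n")
                    writer.writerow(header)
                writer.writerow(record.to_row())
            break
        except OSError as exc:  # pragma: no cover - contention is environment-specific
            last_error = exc
            time.sleep(0.05 * (attempt + 1))
    else:  # pragma: no cover
        raise VersioningError(f"{library_path}: could not append after {retries} tries") from last_error

    records = load_library(library_path, Privilege.ALL, record.user)
    own = sum(1 for r in records if r.user == record.user)
    return own, len(records)


def load_library(
    library_path: str, privilege: Privilege = Privilege.ALL, user: str = ""
) -> list[PlanRecord]:
    """Load records; OWN_ONLY keeps only rows written by *user*.

    Malformed rows are skipped with a logged warning, not fatal.
    """
    header = _read_header(library_path)
    records: list[PlanRecord] = []
    skipped = 0
    with open(library_path, "r", encoding="utf-8", newline="") as fh:
        fh.readline()  # schema
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if not row:
                continue
            try:
                records.append(_parse_row(header, row))
            except (ValidationError, ValueError) as exc:
                skipped += 1
                log.warning("skipping malformed library row: %s", exc)
    if skipped:
        log.warning("%d malformed row(s) skipped in %s", skipped, library_path)
    if privilege == Privilege.OWN_ONLY:
        records = [r for r in records if r.user == user]
    return records


def parse_preferences(text: str) -> dict[str, str]:
    """Parse the flat key=value part of a preferences file.

    Section headers (``[sanity]`` etc.) and their contents are ignored here;
    :func:`planwatch.sanity.parse_sanity_rules` reads the sanity section.
    Recognized keys: export_drawer, export_file, privilege, user.
    """
    prefs: dict[str, str] = {}
    in_section = False
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            in_section = True
            continue
        if not in_section and "=" in line:
            key, _, value = line.partition("=")
            prefs[key.strip()] = value.strip()
    return prefs


@dataclass(frozen=True)
class LibraryFilter:
    """Conjunction of similarity predicates; None fields mean 'any'."""

    protocol: str
    laterality: str | None = None
    has_boost: bool | None = None
    has_nodes: bool | None = None
    breast_modifier: str | None = None
    technique: str | None = None
    require_modifiers: frozenset[str] = frozenset()
    forbid_modifiers: frozenset[str] = frozenset()
    user_scope: Privilege = Privilege.ALL
    user: str = ""

    def matches(self, r: PlanRecord) -> bool:
        if r.protocol != self.protocol:
            return False
        if self.laterality is not None and r.laterality != self.laterality:
            return False
        if self.has_boost is not None and r.has_boost != self.has_boost:
            return False
        if self.has_nodes is not None and r.has_nodes != self.has_nodes:
            return False
        if self.breast_modifier is not None and r.breast_modifier != self.breast_modifier:
            return False
        if self.technique is not None and r.technique != self.technique:
            return False
        if not self.require_modifiers <= r.technique_modifiers:
            return False
        if self.forbid_modifiers & r.technique_modifiers:
            return False
        if self.user_scope == Privilege.OWN_ONLY and r.user != self.user:
            return False
        return True


def filter_similar(records: list[PlanRecord], f: LibraryFilter) -> list[PlanRecord]:
    """Records satisfying every predicate, ordered by timestamp ascending."""
    return sorted((r for r in records if f.matches(r)), key=lambda r: r.timestamp)


def write_library(library_path: str, records: list[PlanRecord]) -> None:
    """Write a whole library in one pass (all records must share columns)."""
    if not records:
        raise ValidationError("cannot write an empty library")
    header = _header_for(records[0])
    for r in records[1:]:
        if _header_for(r) != header:
            raise VersioningError("records disagree on metric columns")
    with open(library_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(SCHEMA_LINE + "\n")
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            writer.writerow(r.to_row())


def latest_only(records: list[PlanRecord]) -> list[PlanRecord]:
    """Collapse duplicate plan_ids to the most recent export."""
    latest: dict[str, PlanRecord] = {}
    for r in sorted(records, key=lambda r: r.timestamp):
        latest[r.plan_id] = r
    return sorted(latest.values(), key=lambda r: r.timestamp)
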