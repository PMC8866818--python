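"""Source-table loading, field harmonization, and pseudonymous IRI minting.

Heterogeneous source tables name the same measurement differently (one study
stores the MoCA category-fluency score as ``MOCA_words_total``, another as
``MCAVF``). Harmonization maps ``(source, header)`` pairs onto a shared
catalogue of semantic pattern keys; unmapped headers are reported, never
silently dropped, and out-of-range cells are quarantined to an exceptions
report rather than ingested.

Subject identifiers are replaced by pseudonymous IRIs derived with a keyed
one-way digest, so the raw study identifier never enters the knowledge graph.
"""

from __future__ import annotations

import csv
import hashlib
import hmac
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from rdflib import URIRef

__all__ = [
    "SourceTable",
    "FieldMapping",
    "PseudonymPolicy",
    "HarmonizationReport",
    "ConfigError",
    "LoadError",
    "PolicyError",
    "PATTERN_CATALOGUE",
    "load_source_table",
    "load_mapping_config",
    "validate_mappings",
    "resolve_field",
    "mint_subject_iri",
    "harmonize",
]


class ConfigError(ValueError):
    """Invalid or ambiguous mapping configuration."""


class LoadError(ValueError):
    """Source table cannot be loaded under the CSV contract."""


class PolicyError(ValueError):
    """Invalid pseudonymization policy."""


#: Registered pattern keys → (value type, valid range or None).
#: Only the MoCA keys are mapped by default; the other instruments are
#: admissible keys that ship unmapped (cross-instrument aggregation is out
#: of scope).
PATTERN_CATALOGUE: dict[str, tuple[str, tuple[float, float] | None]] = {
    "subject_id": ("text", None),
    "group_label": ("text", None),
    "sex": ("text", None),
    "age_years": ("decimal", (0, 120)),
    "education_years": ("decimal", (0, 30)),
    "hoehn_yahr": ("decimal", (0, 5)),
    "moca_total": ("integer", (0, 30)),
    "moca_category_fluency": ("integer", (0, 60)),
    "volume_left_hippocampus": ("decimal", (0, float("inf"))),
    "volume_right_hippocampus": ("decimal", (0, float("inf"))),
    "icv": ("decimal", (0, float("inf"))),
    # admissible instrument keys, unmapped by default
    "rbans_total": ("integer", (0, 160)),
    "hvlt_r_total": ("integer", (0, 36)),
    "upsit_total": ("integer", (0, 40)),
    "trailmaking_a_seconds": ("decimal", (0, 600)),
    "trailmaking_b_seconds": ("decimal", (0, 600)),
    "stroop_interference": ("decimal", None),
    "letter_number_sequencing": ("integer", (0, 30)),
    "benton_jlo": ("integer", (0, 30)),
    "symbol_digit": ("integer", (0, 150)),
    "phonemic_fluency": ("integer", (0, 60)),
}


@dataclass
class SourceTable:
    """One source CSV held as untyped text cells until harmonized."""

    source_name: str
    headers: list[str]
    rows: list[list[str]]
    subject_id_column: str

    def __post_init__(self) -> None:
        if len(set(self.headers)) != len(self.headers):
            raise LoadError(f"{self.source_name}: duplicate headers in {self.headers}")
        if self.subject_id_column not in self.headers:
            raise LoadError(
                f"{self.source_name}: subject id column {self.subject_id_column!r} "
                f"not among headers"
            )
        for i, row in enumerate(self.rows):
            if len(row) != len(self.headers):
                raise LoadError(
                    f"{self.source_name}: row {i} has {len(row)} cells, "
                    f"expected {len(self.headers)}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.headers, dtype=str)


@dataclass(frozen=True)
class FieldMapping:
    """(source, header) → pattern-key harmonization unit."""

    source_name: str
    source_header: str
    pattern_key: str
    value_type: str = "text"
    valid_range: tuple[float, float] | None = None
    value_map: tuple[tuple[str, str], ...] | None = None  # source code → harmonized value


@dataclass(frozen=True)
class PseudonymPolicy:
    """Keyed pseudonymization: salt + namespace for minted subject IRIs."""

    secret_salt: str
    namespace: str = "https://w3id.org/neurokg/instance/"

    def __post_init__(self) -> None:
        if not self.secret_salt:
            raise PolicyError("pseudonym salt must be non-empty")
        if "://" not in self.namespace:
            raise PolicyError(f"namespace must be an absolute IRI: {self.namespace!r}")


@dataclass
class HarmonizationReport:
    """Totality accounting: every header is either mapped or listed unmapped."""

    mapped: dict[str, list[str]] = field(default_factory=dict)    # source → headers
    unmapped: dict[str, list[str]] = field(default_factory=dict)  # source → headers
    exceptions: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    # (source, row index, header, raw value, reason)
    skipped_missing: int = 0


def load_source_table(path: str | Path, source_name: str, subject_id_column: str) -> SourceTable:
    """Read a UTF-8 CSV with a header row into a :class:`SourceTable`.

    Cells stay as text; typing happens during harmonization. Duplicate
    headers or a missing subject-id column raise :class:`LoadError`.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            headers = next(reader)
        except StopIteration:
            raise LoadError(f"{path}: empty file, expected a header row") from None
        rows = [row for row in reader if row]
    return SourceTable(
        source_name=source_name,
        headers=headers,
        rows=rows,
        subject_id_column=subject_id_column,
    )


def load_mapping_config(path: str | Path) -> list[FieldMapping]:
    """Read field mappings from a YAML/JSON config ({mappings: [...]})."""
    with Path(path).open(encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict) or "mappings" not in doc:
        raise ConfigError(f"{path}: expected a mapping document with a 'mappings' list")
    mappings = []
    for entry in doc["mappings"]:
        rng = entry.get("range")
        value_map = entry.get("value_map")
        mappings.append(
            FieldMapping(
                source_name=str(entry["source"]),
                source_header=str(entry["header"]),
                pattern_key=str(entry["pattern_key"]),
                value_type=str(entry.get("type", "text")),
                valid_range=tuple(rng) if rng else None,
                value_map=tuple(sorted((str(k), str(v)) for k, v in value_map.items()))
                if value_map
                else None,
            )
        )
    return validate_mappings(mappings)


def validate_mappings(mappings: Sequence[FieldMapping]) -> list[FieldMapping]:
    """Reject duplicate (source, header) pairs and unknown pattern keys."""
    seen: dict[tuple[str, str], str] = {}
    for m in mappings:
        key = (m.source_name, m.source_header)
        if key in seen and seen[key] != m.pattern_key:
            raise ConfigError(
                f"ambiguous mapping for {key}: {seen[key]!r} vs {m.pattern_key!r}"
            )
        seen[key] = m.pattern_key
        if m.pattern_key not in PATTERN_CATALOGUE:
            raise ConfigError(
                f"unknown pattern key {m.pattern_key!r} for {key}; "
                f"registered keys: {sorted(PATTERN_CATALOGUE)}"
            )
        if m.value_type not in ("integer", "decimal", "text"):
            raise ConfigError(f"unknown value type {m.value_type!r} for {key}")
    return list(mappings)


def resolve_field(
    source_name: str, header: str, config: Sequence[FieldMapping]
) -> str | None:
    """Deterministic (source, header) → pattern-key lookup; None if unmapped."""
    for m in config:
        if m.source_name == source_name and m.source_header == header:
            return m.pattern_key
    return None


def mint_subject_iri(
    source_name: str, source_subject_id: str, policy: PseudonymPolicy
) -> URIRef:
    """Deterministic pseudonymous subject IRI.

    A keyed BLAKE2b digest of (source, id) is embedded in the policy
    namespace; identical inputs always give the same IRI, and the raw
    subject id never appears in it (a rare accidental substring hit is
    resolved by deterministic re-digesting).
    """
    if not source_name or not source_subject_id:
        raise ValueError("source name and subject id must be non-empty")
    if not policy.secret_salt:
        raise PolicyError("pseudonym salt must be non-empty")
    for attempt in range(64):
        message = f"{source_name}\x1f{source_subject_id}\x1f{attempt}".encode("utf-8")
        digest = hmac.new(
            policy.secret_salt.encode("utf-8"), message, hashlib.blake2b
        ).hexdigest()[:20]
        iri = f"{policy.namespace}subj-{digest}"
        if source_subject_id not in iri:
            return URIRef(iri)
    raise PolicyError(
        f"cannot mint a non-leaking IRI for subject id {source_subject_id!r} "
        "(id collides with the namespace text)"
    )


def _type_cell(raw: str, value_type: str):
    raw = raw.strip()
    if raw == "" or raw.upper() in ("NA", "NAN", "NULL"):
        return None
    if value_type == "integer":
        return int(round(float(raw)))
    if value_type == "decimal":
        return float(raw)
    return raw


def harmonize(
    tables: Sequence[SourceTable],
    config: Sequence[FieldMapping],
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Harmonize source tables into one typed long-format DataFrame.

    Returns a frame with columns ``source``, ``row_index``, ``subject_id``
    plus one column per pattern key seen, and a report accounting for every
    header (mapped or unmapped) and every quarantined out-of-range cell.
    Missing cells stay missing — no sentinel values are invented.
    """
    config = validate_mappings(config)
    report = HarmonizationReport()
    records: list[dict] = []

    for table in tables:
        mapped_headers, unmapped_headers = [], []
        header_keys: dict[str, str] = {}
        for header in table.headers:
            if header == table.subject_id_column:
                header_keys[header] = "subject_id"
                mapped_headers.append(header)
                continue
            key = resolve_field(table.source_name, header, config)
            if key is None:
                unmapped_headers.append(header)
            else:
                header_keys[header] = key
                mapped_headers.append(header)
        report.mapped[table.source_name] = mapped_headers
        report.unmapped[table.source_name] = unmapped_headers

        mapping_by_header = {
            m.source_header: m for m in config if m.source_name == table.source_name
        }
        for row_index, row in enumerate(table.rows):
            record: dict = {"source": table.source_name, "row_index": row_index}
            for header, raw in zip(table.headers, row):
                key = header_keys.get(header)
                if key is None:
                    continue
                if key == "subject_id":
                    record["subject_id"] = raw.strip()
                    continue
                m = mapping_by_header[header]
                raw_value = raw
                if m.value_map is not None:
                    raw_value = dict(m.value_map).get(raw.strip(), raw)
                try:
                    value = _type_cell(str(raw_value), m.value_type)
                except ValueError:
                    report.exceptions.append(
                        (table.source_name, row_index, header, raw, "unparseable")
                    )
                    continue
                if value is None:
                    report.skipped_missing += 1
                    continue
                valid_range = m.valid_range or PATTERN_CATALOGUE[key][1]
                if (
                    valid_range is not None
                    and not isinstance(value, str)
                    and not (valid_range[0] <= value <= valid_range[1])
                ):
                    report.exceptions.append(
                        (table.source_name, row_index, header, raw, "out of range")
                    )
                    continue
                record[key] = value
            records.append(record)

    frame = pd.DataFrame.from_records(records)
    return frame, report
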