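"""FHIR-style Observation subset used as the lingua franca between layers.

The in-memory model targets the R4 ``Observation`` resource shape restricted
to the seven fields the pipeline needs: an observation category code, the
patient identifier (``subject``), a timezone-aware ``effective_time``, a
device descriptor, and an ordered list of components.  Each component carries
a LOINC code, a display name, a typed value and a UCUM unit.  Records are
exchanged as newline-delimited JSON (one observation per line).

The :class:`CodeRegistry` maps canonical physiological parameter names
(``"HR"``, ``"SaO2"``, ...) to their LOINC code, UCUM unit and value type.
It ships as a versioned JSON asset; codes other than the well-known vital
signs are filled from the public LOINC table and flagged with provenance
``"external-standard"`` in the asset.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import IO, Any, Iterable, Union

__all__ = [
    "ValidationError",
    "UnknownParameterError",
    "NdjsonParseError",
    "ObservationComponent",
    "Device",
    "ObservationRecord",
    "CodeRegistry",
    "CodeEntry",
    "make_observation",
    "default_code_registry",
    "write_ndjson",
    "read_ndjson",
    "record_to_dict",
    "record_from_dict",
]

# LOINC codes are 1-7 digits, a hyphen, and a single check digit.
LOINC_PATTERN = re.compile(r"^\d{1,7}-\d$")

#: FHIR value kinds supported for components (subset of the standard set).
VALUE_TYPES = ("decimal", "integer", "string", "boolean", "range")


class ValidationError(ValueError):
    """A record or component violates a model invariant."""


class UnknownParameterError(KeyError):
    """A canonical parameter name is not present in the code registry."""


class NdjsonParseError(ValueError):
    """A line of an NDJSON stream could not be parsed.

    Attributes
    ----------
    line_number : int
        1-based index of the offending line.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _is_finite_number(x: Any) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool) and math.isfinite(x)


@dataclass
class ObservationComponent:
    """One physiological parameter inside an observation.

    ``value`` is a decimal, integer, string, boolean, or a range expressed
    as a ``{"low": .., "high": ..}`` mapping.  A UCUM ``unit`` is mandatory
    whenever the value is numeric.
    """

    code: str
    display: str
    value: Any
    unit: str | None = None

    def __post_init__(self) -> None:
        if not LOINC_PATTERN.match(self.code):
            raise ValidationError(f"component code {self.code!r} is not LOINC-shaped")
        if isinstance(self.value, dict):
            if set(self.value) != {"low", "high"}:
                raise ValidationError("range value must have exactly 'low' and 'high'")
            if not all(_is_finite_number(v) for v in self.value.values()):
                raise ValidationError("range bounds must be finite numbers")
            if self.value["low"] > self.value["high"]:
                raise ValidationError("range low must not exceed high")
            if self.unit is None:
                raise ValidationError("numeric (range) value requires a unit")
        elif isinstance(self.value, bool) or isinstance(self.value, str):
            pass
        elif isinstance(self.value, (int, float)):
            if not math.isfinite(self.value):
                raise ValidationError(f"non-finite numeric value for {self.code}")
            if self.unit is None:
                raise ValidationError(f"numeric value for {self.code} requires a unit")
        else:
            raise ValidationError(
                f"unsupported value type {type(self.value).__name__} for {self.code}"
            )

    @property
    def value_kind(self) -> str:
        if isinstance(self.value, dict):
            return "range"
        if isinstance(self.value, bool):
            return "boolean"
        if isinstance(self.value, int):
            return "integer"
        if isinstance(self.value, float):
            return "decimal"
        return "string"


@dataclass
class Device:
    """Device descriptor: type string and location (bed)."""

    type: str
    location: str = ""


@dataclass
class ObservationRecord:
    """A FHIR-style observation: category code, subject, time, device, components."""

    code: str
    subject: str
    effective_time: datetime
    device: Device
    components: list[ObservationComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject:
            raise ValidationError("subject must be non-empty")
        if not isinstance(self.effective_time, datetime):
            raise ValidationError("effective_time must be a datetime")
        if self.effective_time.tzinfo is None:
            raise ValidationError("effective_time must be timezone-aware")
        if not self.components:
            raise ValidationError("components must be non-empty")
        codes = [c.code for c in self.components]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate component codes: {dupes}")


def make_observation(
    code: str,
    subject: str,
    time: Union[datetime, str],
    device: Device,
    components: Iterable[ObservationComponent],
) -> ObservationRecord:
    """Construct a validated :class:`ObservationRecord`.

    ``time`` may be a timezone-aware datetime or an ISO 8601 string
    (a trailing ``Z`` is accepted).  Component insertion order is preserved.
    """
    if isinstance(time, str):
        try:
            time = datetime.fromisoformat(time.replace("Z", "+00:00"))
        except ValueError as exc:
            raise ValidationError(f"malformed timestamp {time!r}: {exc}") from exc
    return ObservationRecord(
        code=code,
        subject=subject,
        effective_time=time,
        device=device,
        components=list(components),
    )


# ---------------------------------------------------------------------------
# Code registry (canonical parameter name -> LOINC code, UCUM unit, type)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeEntry:
    loinc: str
    unit: str
    value_type: str
    display: str
    provenance: str = "external-standard"


class CodeRegistry:
    """Total lookup from canonical parameter names to (LOINC, UCUM, type)."""

    def __init__(self, entries: dict[str, CodeEntry], version: str = "0"):
        codes = [e.loinc for e in entries.values()]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate LOINC codes in registry: {dupes}")
        for name, e in entries.items():
            if not LOINC_PATTERN.match(e.loinc):
                raise ValidationError(f"{name}: code {e.loinc!r} is not LOINC-shaped")
            if e.value_type not in VALUE_TYPES:
                raise ValidationError(f"{name}: unknown value type {e.value_type!r}")
        self.entries = dict(entries)
        self.version = version
        self._by_code = {e.loinc: name for name, e in entries.items()}

    def lookup_code(self, name: str) -> tuple[str, str]:
        """Return ``(LOINC code, UCUM unit)`` for a canonical parameter name."""
        entry = self.lookup_entry(name)
        return entry.loinc, entry.unit

    def lookup_entry(self, name: str) -> CodeEntry:
        try:
            return self.entries[name]
        except KeyError:
            raise UnknownParameterError(
                f"parameter {name!r} is not in the code registry "
                f"(version {self.version})"
            ) from None

    def name_for_code(self, loinc: str) -> str:
        try:
            return self._by_code[loinc]
        except KeyError:
            raise UnknownParameterError(f"LOINC code {loinc!r} not in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "CodeRegistry":
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        else:
            payload = json.load(source)
        entries = {
            name: CodeEntry(
                loinc=spec["loinc"],
                unit=spec["unit"],
                value_type=spec["value_type"],
                display=spec.get("display", name),
                provenance=spec.get("provenance", "external-standard"),
            )
            for name, spec in payload["entries"].items()
        }
        return cls(entries, version=str(payload.get("version", "0")))


def default_code_registry() -> CodeRegistry:
    """Load the registry asset shipped with the package."""
    ref = resources.files("icufusion").joinpath("data/loinc_registry.json")
    with ref.open("r", encoding="utf-8") as fh:
        return CodeRegistry.from_json(fh)


# ---------------------------------------------------------------------------
# NDJSON serialization
# ---------------------------------------------------------------------------


def record_to_dict(record: ObservationRecord) -> dict:
    return {
        "code": record.code,
        "subject": record.subject,
        "effectiveDateTime": record.effective_time.isoformat(),
        "device": {"type": record.device.type, "location": record.device.location},
        "components": [
            {"code": c.code, "display": c.display, "value": c.value, "unit": c.unit}
            for c in record.components
        ],
    }


def record_from_dict(payload: dict) -> ObservationRecord:
    device = Device(
        type=payload["device"]["type"], location=payload["device"].get("location", "")
    )
    components = [
        ObservationComponent(
            code=c["code"], display=c["display"], value=c["value"], unit=c.get("unit")
        )
        for c in payload["components"]
    ]
    return make_observation(
        code=payload["code"],
        subject=payload["subject"],
        time=payload["effectiveDateTime"],
        device=device,
        components=components,
    )


def write_ndjson(records: Iterable[ObservationRecord], sink: Union[str, Path, IO[str]]) -> int:
    """Write one JSON object per record per line; returns the line count."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            return write_ndjson(records, fh)
    n = 0
    for record in records:
        sink.write(json.dumps(record_to_dict(record), separators=(",", ":")) + "\n")
        n += 1
    return n


def read_ndjson(source: Union[str, Path, IO[str]]) -> list[ObservationRecord]:
    """Parse an NDJSON stream of observations; errors carry the line number."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_ndjson(fh)
    records = []
    for i, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            payload = json.loads(line)
        except json.JSONDecodeError as exc:
            raise NdjsonParseError(f"invalid JSON: {exc.msg}", line_number=i) from exc
        try:
            records.append(record_from_dict(payload))
        except (KeyError, TypeError, ValidationError) as exc:
            raise NdjsonParseError(f"invalid observation: {exc}", line_number=i) from exc
    return records
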