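"""Device-feature management and multi-dialect message translation.

Bedside devices speak three dialects:

* ``hl7v2`` — pipe-delimited MSH+OBX segments (patient monitors).  The
  subset understood here is: segment separator CR/LF, field separator ``|``,
  component separator ``^``; OBX-3 carries the device's observation code,
  OBX-5 the value, OBX-6 the unit; MSH-7 carries the device timestamp.
* ``json`` — key/value payloads (infusion pumps); locators are dot-separated
  key paths.
* ``proprietary`` — ``LABEL<kv-delim>VALUE`` tokens joined by a field
  delimiter, both delimiters declared per device category (ventilators,
  hematology analyzers, hemodynamics monitors).

Each mappable datum of a dialect is a *device feature* (DF) registered in a
:class:`DeviceFeatureRegistry`.  A deterministic, table-driven parser is
compiled from the registered DFs — same registry in, byte-identical rules
out — and drives :func:`parse_message` / :func:`translate`, which emit
FHIR-style :class:`~icufusion.fhir_model.ObservationRecord` objects.
Out-of-range values are flagged and forwarded, never dropped: clinical
extremes are signal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import IO, Any, Optional, Union

from .fhir_model import (
    CodeRegistry,
    Device,
    ObservationComponent,
    ObservationRecord,
    ValidationError,
    make_observation,
)

__all__ = [
    "DIALECTS",
    "DeviceFeature",
    "DeviceFeatureRegistry",
    "ParserRules",
    "RawMessage",
    "ParsedValue",
    "ParseResult",
    "ParseError",
    "DialectMismatchError",
    "EmptyCategoryError",
    "EmptyTranslationError",
    "compile_parser",
    "parse_message",
    "translate",
    "default_feature_registry",
    "read_raw_ndjson",
    "write_raw_ndjson",
]

logger = logging.getLogger(__name__)

DIALECTS = ("hl7v2", "json", "proprietary")

#: Observation category attached to translated records, per device category.
OBSERVATION_CATEGORY = {
    "patient_monitor": "vital-signs",
    "ventilator": "ventilator",
    "hemodynamics": "hemodynamics",
    "infusion_pump": "infusion",
    "hematology": "laboratory",
}
DEFAULT_OBSERVATION_CATEGORY = "device-measurement"


class ParseError(ValueError):
    """Payload could not be decoded; carries the character offset."""

    def __init__(self, message: str, offset: int = 0):
        super().__init__(f"offset {offset}: {message}")
        self.offset = offset


class DialectMismatchError(ValueError):
    """Message dialect does not match the compiled rules' dialect."""


class EmptyCategoryError(ValueError):
    """No device features are registered for the requested category/dialect."""


class EmptyTranslationError(ValueError):
    """No registered feature could be extracted from the payload."""


@dataclass(frozen=True)
class DeviceFeature:
    """One mappable datum of a device dialect.

    ``field_locator`` is dialect-specific: the OBX-3 code for ``hl7v2``, a
    dot-separated key path for ``json``, and the token label for
    ``proprietary``.  ``name`` must be a canonical parameter name known to
    the code registry.
    """

    category: str
    name: str
    dialect: str
    field_locator: str
    value_type: str = "decimal"
    value_range: Optional[tuple[float, float]] = None
    delimiter: Optional[str] = None
    kv_delimiter: str = ":"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if self.value_type not in ("decimal", "integer", "string"):
            raise ValidationError(f"unknown value type {self.value_type!r}")
        if self.value_range is not None:
            low, high = self.value_range
            if not low < high:
                raise ValidationError(
                    f"{self.category}/{self.name}: range low {low} must be < high {high}"
                )
        if self.dialect == "proprietary" and not self.delimiter:
            raise ValidationError(
                f"{self.category}/{self.name}: proprietary dialect requires a delimiter"
            )


class DeviceFeatureRegistry:
    """Registry of device features keyed by ``(category, name)``.

    Re-registering an existing key replaces the feature and appends an
    audit-log entry recording both versions.
    """

    def __init__(self) -> None:
        self._features: dict[tuple[str, str], DeviceFeature] = {}
        self.audit_log: list[dict] = []

    def register(self, df: DeviceFeature) -> "DeviceFeatureRegistry":
        key = (df.category, df.name)
        if key in self._features and self._features[key] != df:
            self.audit_log.append(
                {
                    "action": "replace",
                    "category": df.category,
                    "name": df.name,
                    "previous": asdict(self._features[key]),
                    "new": asdict(df),
                }
            )
            logger.info("replacing device feature %s/%s", df.category, df.name)
        self._features[key] = df
        return self

    def features_for(self, category: str, dialect: str) -> list[DeviceFeature]:
        return [
            df
            for (cat, _), df in sorted(self._features.items())
            if cat == category and df.dialect == dialect
        ]

    def categories(self) -> list[str]:
        return sorted({cat for cat, _ in self._features})

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features.values())

    def to_json(self, sink: Union[str, Path, IO[str]]) -> None:
        payload = {
            "version": "1",
            "features": [asdict(df) for df in sorted(self, key=lambda d: (d.category, d.name))],
        }
        if isinstance(sink, (str, Path)):
            with open(sink, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1)
        else:
            json.dump(payload, sink, indent=1)

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "DeviceFeatureRegistry":
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        else:
            payload = json.load(source)
        registry = cls()
        for spec in payload["features"]:
            rng = spec.get("value_range")
            registry.register(
                DeviceFeature(
                    category=spec["category"],
                    name=spec["name"],
                    dialect=spec["dialect"],
                    field_locator=spec["field_locator"],
                    value_type=spec.get("value_type", "decimal"),
                    value_range=tuple(rng) if rng else None,
                    delimiter=spec.get("delimiter"),
                    kv_delimiter=spec.get("kv_delimiter", ":"),
                )
            )
        return registry


def default_feature_registry() -> DeviceFeatureRegistry:
    """Load the device-feature registry asset shipped with the package."""
    ref = resources.files("icufusion").joinpath("data/device_features.json")
    with ref.open("r", encoding="utf-8") as fh:
        return DeviceFeatureRegistry.from_json(fh)


@dataclass(frozen=True)
class ParserRules:
    """Deterministic extraction rules compiled from registered DFs.

    ``compiled_at`` is a content fingerprint (sha256 of the rules), so
    recompiling an unchanged registry yields byte-identical rules.
    """

    category: str
    dialect: str
    rules: tuple[DeviceFeature, ...]
    compiled_at: str = ""

    def __post_init__(self) -> None:
        if not self.compiled_at:
            digest = hashlib.sha256(
                json.dumps([asdict(r) for r in self.rules], sort_keys=True).encode()
            ).hexdigest()
            object.__setattr__(self, "compiled_at", digest)


def compile_parser(
    category: str,
    dialect: str,
    registry: DeviceFeatureRegistry,
    code_registry: Optional[CodeRegistry] = None,
) -> ParserRules:
    """Compile extraction rules covering exactly the registered DFs.

    Pure: the same registry contents always produce identical rules.  When a
    code registry is supplied, every rule's canonical name must resolve in it.
    """
    features = registry.features_for(category, dialect)
    if not features:
        raise EmptyCategoryError(
            f"no device features registered for category {category!r}, dialect {dialect!r}"
        )
    locators = [df.field_locator for df in features]
    if len(set(locators)) != len(locators):
        dupes = sorted({l for l in locators if locators.count(l) > 1})
        raise ValidationError(f"ambiguous rules: locators {dupes} map to multiple names")
    if code_registry is not None:
        for df in features:
            code_registry.lookup_entry(df.name)  # raises UnknownParameterError
    return ParserRules(category=category, dialect=dialect, rules=tuple(features))


@dataclass
class RawMessage:
    """A raw device message as received from the gateway."""

    category: str
    dialect: str
    payload: str
    received_time: datetime
    source_device_id: str = ""
    patient_id: str = ""
    location: str = ""

    def __post_init__(self) -> None:
        if not self.payload:
            raise ValidationError("payload must be non-empty")
        if self.dialect not in DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")


@dataclass(frozen=True)
class ParsedValue:
    name: str
    value: Any
    flags: tuple[str, ...] = ()


@dataclass
class ParseResult:
    values: list[ParsedValue]
    residue: list[str] = field(default_factory=list)
    device_time: Optional[datetime] = None


def _convert(raw: str, df: DeviceFeature, offset: int) -> Any:
    raw = raw.strip()
    try:
        if df.value_type == "integer":
            return int(raw)
        if df.value_type == "decimal":
            return float(raw)
        return raw
    except ValueError as exc:
        raise ParseError(
            f"cannot convert {raw!r} to {df.value_type} for {df.name}", offset
        ) from exc


def _check_range(value: Any, df: DeviceFeature) -> tuple[str, ...]:
    if df.value_range is not None and isinstance(value, (int, float)):
        low, high = df.value_range
        if not (low <= value <= high):
            return ("out_of_range",)
    return ()


def _parse_hl7_timestamp(ts: str) -> Optional[datetime]:
    ts = ts.strip()
    tz = timezone.utc
    for sign in ("+", "-"):
        if sign in ts[8:]:
            idx = ts.index(sign, 8)
            ts, off = ts[:idx], ts[idx:]
            try:
                delta = int(off[1:3]) * 60 + int(off[3:5])
                if off[0] == "-":
                    delta = -delta
                tz = timezone(timedelta(minutes=delta))
            except (ValueError, IndexError):
                return None
            break
    for fmt in ("%Y%m%d%H%M%S", "%Y%m%d%H%M"):
        try:
            return datetime.strptime(ts, fmt).replace(tzinfo=tz)
        except ValueError:
            continue
    return None


def _parse_hl7v2(payload: str, rules: ParserRules) -> ParseResult:
    by_locator = {df.field_locator: df for df in rules.rules}
    values: list[ParsedValue] = []
    residue: list[str] = []
    device_time: Optional[datetime] = None
    segments = [s for s in payload.replace("\r\n", "\r").replace("\n", "\r").split("\r") if s]
    saw_obx = False
    for seg in segments:
        fields = seg.split("|")
        seg_type = fields[0]
        if seg_type == "MSH":
            # MSH-1 is the field separator itself, so index 6 is MSH-7.
            if len(fields) > 6 and fields[6]:
                device_time = _parse_hl7_timestamp(fields[6])
            continue
        if seg_type != "OBX":
            residue.append(seg)
            continue
        saw_obx = True
        if len(fields) < 6:
            raise ParseError(f"OBX segment too short: {seg!r}", payload.find(seg))
        code = fields[3].split("^")[0]
        raw_value = fields[5]
        df = by_locator.get(code)
        if df is None:
            residue.append(seg)
            continue
        value = _convert(raw_value, df, payload.find(seg))
        values.append(ParsedValue(df.name, value, _check_range(value, df)))
    if not segments or not saw_obx:
        raise ParseError("no OBX segments found in HL7 payload", 0)
    return ParseResult(values=values, residue=residue, device_time=device_time)


def _walk_path(payload: dict, path: str) -> Any:
    node: Any = payload
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            return None
        node = node[part]
    return node


def _parse_json(payload: str, rules: ParserRules) -> ParseResult:
    try:
        doc = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc.msg}", exc.pos) from exc
    if not isinstance(doc, dict):
        raise ParseError("JSON payload must be an object", 0)
    values: list[ParsedValue] = []
    matched_roots = set()
    device_time: Optional[datetime] = None
    for df in rules.rules:
        raw = _walk_path(doc, df.field_locator)
        if raw is None:
            continue
        matched_roots.add(df.field_locator.split(".")[0])
        value = _convert(str(raw), df, 0)
        values.append(ParsedValue(df.name, value, _check_range(value, df)))
    ts = doc.get("time") or doc.get("timestamp")
    if isinstance(ts, str):
        try:
            device_time = datetime.fromisoformat(ts.replace("Z", "+00:00"))
            if device_time.tzinfo is None:
                device_time = device_time.replace(tzinfo=timezone.utc)
        except ValueError:
            device_time = None
    residue = [k for k in doc if k not in matched_roots and k not in ("time", "timestamp")]
    return ParseResult(values=values, residue=residue, device_time=device_time)


def _parse_proprietary(payload: str, rules: ParserRules) -> ParseResult:
    field_delim = rules.rules[0].delimiter or "|"
    kv_delim = rules.rules[0].kv_delimiter
    by_label = {df.field_locator: df for df in rules.rules}
    values: list[ParsedValue] = []
    residue: list[str] = []
    offset = 0
    for token in payload.split(field_delim):
        if not token.strip():
            offset += len(token) + len(field_delim)
            continue
        if kv_delim not in token:
            raise ParseError(f"token {token!r} lacks delimiter {kv_delim!r}", offset)
        label, raw = token.split(kv_delim, 1)
        df = by_label.get(label.strip())
        if df is None:
            residue.append(token)
        else:
            value = _convert(raw, df, offset)
            values.append(ParsedValue(df.name, value, _check_range(value, df)))
        offset += len(token) + len(field_delim)
    return ParseResult(values=values, residue=residue)


_PARSERS = {"hl7v2": _parse_hl7v2, "json": _parse_json, "proprietary": _parse_proprietary}


def parse_message(msg: RawMessage, rules: ParserRules) -> ParseResult:
    """Extract (canonical name, typed value) pairs from a raw message.

    Out-of-range values are flagged, not dropped.  Unmatched payload tokens
    are reported in ``residue``.
    """
    if msg.dialect != rules.dialect:
        raise DialectMismatchError(
            f"message dialect {msg.dialect!r} != rules dialect {rules.dialect!r}"
        )
    return _PARSERS[msg.dialect](msg.payload, rules)


def translate(
    msg: RawMessage, rules: ParserRules, code_registry: CodeRegistry
) -> ObservationRecord:
    """Translate a raw device message into one FHIR-style observation.

    Components carry the parsed values bit-identically, coded per the
    registry; ``effective_time`` is the device-reported time when present,
    otherwise the gateway receive time.  A missing patient identifier maps
    to subject ``"UNKNOWN"`` with a warning (device streams can outpace ADT
    linkage).
    """
    result = parse_message(msg, rules)
    if not result.values:
        raise EmptyTranslationError(
            f"no registered features extractable from {msg.category} payload"
        )
    subject = msg.patient_id
    if not subject:
        warnings.warn(
            f"message from {msg.source_device_id or 'unknown device'} has no "
            "patient identifier; using subject='UNKNOWN'",
            stacklevel=2,
        )
        subject = "UNKNOWN"
    components = []
    for pv in result.values:
        code, unit = code_registry.lookup_code(pv.name)
        entry = code_registry.lookup_entry(pv.name)
        components.append(
            ObservationComponent(code=code, display=entry.display, value=pv.value, unit=unit)
        )
    return make_observation(
        code=OBSERVATION_CATEGORY.get(msg.category, DEFAULT_OBSERVATION_CATEGORY),
        subject=subject,
        time=result.device_time or msg.received_time,
        device=Device(type=msg.category, location=msg.location),
        components=components,
    )


# ---------------------------------------------------------------------------
# Raw-message corpora as NDJSON
# ---------------------------------------------------------------------------


def write_raw_ndjson(messages: list[RawMessage], sink: Union[str, Path, IO[str]]) -> int:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            return write_raw_ndjson(messages, fh)
    for msg in messages:
        payload = asdict(msg)
        payload["received_time"] = msg.received_time.isoformat()
        sink.write(json.dumps(payload, separators=(",", ":")) + "\n")
    return len(messages)


def read_raw_ndjson(source: Union[str, Path, IO[str]]) -> list[RawMessage]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_raw_ndjson(fh)
    messages = []
    for i, line in enumerate(source, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            payload = json.loads(line)
            payload["received_time"] = datetime.fromisoformat(payload["received_time"])
            messages.append(RawMessage(**payload))
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"line {i}: {exc}", i) from exc
    return messages
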