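"""Ventilation indices, predicted body weight, safety alerts, patient fusion.

Three indices guide protective ventilation of ARDS patients:

* **Ventilatory ratio** — a dimensionless efficiency index combining minute
  ventilation, arterial CO2 tension and predicted body weight.  The default
  form is ``Ve * PCO2 * Vt / (100 * 37.5 * PBW)`` with Ve in L/min and Vt in
  mL; the conventional bedside form (Ve in mL/min, no tidal-volume factor)
  is available as ``mode="standard"``.
* **P/F ratio** — ``PO2 / FiO2`` in mmHg with FiO2 a fraction in (0, 1];
  values below 300 indicate impaired oxygenation.
* **LTVV** — tidal volume normalized by predicted body weight, ``Vt / PBW``
  in mL/kg; values above 8 are outside the lung-protective zone.

Predicted body weight uses the ARDSNet/Devine formula: males
``50 + 0.91 * (height_cm - 152.4)``, females ``45.5 + 0.91 * (height_cm -
152.4)``; heights below the 152.4 cm anchor floor at the base weight.

Alerts fire on strict violation of the safety thresholds (LTVV > 8 mL/kg,
P/F < 300 mmHg, FiO2 >= 0.4), so a patient sitting exactly on a boundary is
safe.  Vital-sign out-of-range alerts use configurable normal ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Optional

from .fhir_model import CodeRegistry, ObservationRecord, default_code_registry

__all__ = [
    "DomainError",
    "IncompleteStateError",
    "PatientProfile",
    "VentilationState",
    "VitalSample",
    "DerivedIndices",
    "Alert",
    "AlertThresholds",
    "PatientState",
    "pbw",
    "ventilatory_ratio",
    "pf_ratio",
    "ltvv",
    "derive_indices",
    "evaluate_alerts",
    "fuse_patient_state",
]

# Named configuration constants of the ventilatory-ratio denominator:
# predicted minute ventilation is taken as 100 mL/kg/min of PBW, against an
# ideal arterial CO2 tension of 37.5 mmHg.
VR_PREDICTED_VE_ML_PER_KG = 100.0
VR_IDEAL_PCO2_MMHG = 37.5

# ARDSNet/Devine predicted-body-weight anchors.
PBW_BASE_KG = {"male": 50.0, "female": 45.5}
PBW_SLOPE_KG_PER_CM = 0.91
PBW_ANCHOR_HEIGHT_CM = 152.4

WARD_ZONES = ("negative_pressure", "contact_isolation", "regular")


class DomainError(ValueError):
    """An index was evaluated outside its mathematical domain."""


class IncompleteStateError(ValueError):
    """Required fields are missing from a patient state."""

    def __init__(self, missing: list[str]):
        super().__init__(f"missing required fields: {', '.join(sorted(missing))}")
        self.missing = sorted(missing)


@dataclass
class PatientProfile:
    patient_id: str
    sex: str
    height_cm: float
    bed: str = ""
    ward_zone: str = "regular"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not 120 <= self.height_cm <= 230:
            raise DomainError(
                f"height {self.height_cm} cm outside the 120-230 cm validity range"
            )
        if self.ward_zone not in WARD_ZONES:
            raise DomainError(f"unknown ward zone {self.ward_zone!r}")


@dataclass
class VentilationState:
    """Ventilator settings plus blood gas, the inputs of the three indices."""

    Vt: float  # tidal volume, mL
    Ve: float  # exhaled minute volume, L/min
    FiO2: float  # inspired oxygen fraction, (0, 1]
    PCO2: float  # arterial CO2 partial pressure, mmHg
    PO2: float  # arterial O2 partial pressure, mmHg
    PBW: float  # predicted body weight, kg
    timestamp: Optional[datetime] = None

    def __post_init__(self) -> None:
        for name in ("Vt", "Ve", "FiO2", "PCO2", "PO2", "PBW"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise DomainError(f"{name} must be positive, got {value}")
        if self.FiO2 is not None and self.FiO2 > 1:
            raise DomainError(
                f"FiO2 must be a fraction in (0, 1], got {self.FiO2}; "
                "percent inputs are normalized during fusion"
            )


@dataclass
class VitalSample:
    HR: Optional[float] = None  # beats/min
    BP_SYS: Optional[float] = None  # mmHg
    BP_DIA: Optional[float] = None  # mmHg
    RR: Optional[float] = None  # breaths/min
    SpO2: Optional[float] = None  # %

    def __post_init__(self) -> None:
        bounds = {"HR": (0, 300), "SpO2": (0, 100), "RR": (0, 120),
                  "BP_SYS": (0, 400), "BP_DIA": (0, 300)}
        for name, (lo, hi) in bounds.items():
            value = getattr(self, name)
            if value is not None and not lo <= value <= hi:
                raise DomainError(f"{name}={value} outside physiological bounds [{lo}, {hi}]")


@dataclass
class DerivedIndices:
    ventilatory_ratio: float
    pf_ratio: float
    ltvv: float
    timestamp: Optional[datetime] = None


@dataclass
class Alert:
    kind: str  # LTVV_HIGH | PF_LOW | FIO2_HIGH | VITAL_OUT_OF_RANGE
    observed: float
    threshold: float
    direction: str  # "above" or "below"
    timestamp: Optional[datetime] = None
    patient_id: str = ""
    parameter: str = ""


@dataclass
class AlertThresholds:
    """Safety thresholds.  Alerts fire on strict violation."""

    ltvv_max: float = 8.0  # mL/kg; safe when <= 8
    pf_min: float = 300.0  # mmHg; safe when >= 300
    fio2_max: float = 0.4  # fraction; safe when < 0.4
    # Vital normal ranges are configurable conventions, not printed values.
    vital_ranges: dict = field(
        default_factory=lambda: {
            "HR": (60.0, 100.0),
            "RR": (12.0, 20.0),
            "SpO2": (94.0, 100.0),
            "BP_SYS": (90.0, 140.0),
        }
    )


def pbw(sex: str, height_cm: float) -> float:
    """Predicted body weight (kg), ARDSNet/Devine formula.

    Heights below the 152.4 cm anchor return the base weight (floor policy).
    """
    if sex not in PBW_BASE_KG:
        raise DomainError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 120 <= height_cm <= 230:
        raise DomainError(f"height {height_cm} cm outside the 120-230 cm validity range")
    return PBW_BASE_KG[sex] + PBW_SLOPE_KG_PER_CM * max(0.0, height_cm - PBW_ANCHOR_HEIGHT_CM)


def ventilatory_ratio(
    Ve: float, PCO2: float, Vt: float, PBW: float, mode: str = "as_printed"
) -> float:
    """Ventilatory ratio (dimensionless).

    ``mode="as_printed"`` (default): ``Ve * PCO2 * Vt / (100 * 37.5 * PBW)``
    with Ve in L/min and Vt in mL.  ``mode="standard"`` computes the
    conventional index ``(Ve_mL/min * PCO2) / (100 * PBW * 37.5)`` with Ve
    converted from L/min to mL/min and no tidal-volume factor.
    """
    for name, value in (("Ve", Ve), ("PCO2", PCO2), ("Vt", Vt), ("PBW", PBW)):
        if value <= 0:
            raise DomainError(f"{name} must be positive, got {value}")
    denom = VR_PREDICTED_VE_ML_PER_KG * VR_IDEAL_PCO2_MMHG * PBW
    if mode == "as_printed":
        return Ve * PCO2 * Vt / denom
    if mode == "standard":
        return (Ve * 1000.0) * PCO2 / denom
    raise ValueError(f"unknown ventilatory-ratio mode {mode!r}")


def pf_ratio(PO2: float, FiO2: float) -> float:
    """Oxygenation index ``PO2 / FiO2`` in mmHg; FiO2 is a fraction in (0, 1]."""
    if PO2 <= 0:
        raise DomainError(f"PO2 must be positive, got {PO2}")
    if not 0 < FiO2 <= 1:
        raise DomainError(f"FiO2 must be a fraction in (0, 1], got {FiO2}")
    return PO2 / FiO2


def ltvv(Vt: float, PBW: float) -> float:
    """Tidal volume per kg predicted body weight, ``Vt / PBW`` in mL/kg."""
    if Vt <= 0:
        raise DomainError(f"Vt must be positive, got {Vt}")
    if PBW <= 0:
        raise DomainError(f"PBW must be positive, got {PBW}")
    return Vt / PBW


def derive_indices(state: VentilationState, mode: str = "as_printed") -> DerivedIndices:
    missing = [
        name
        for name in ("Vt", "Ve", "FiO2", "PCO2", "PO2", "PBW")
        if getattr(state, name) is None
    ]
    if missing:
        raise IncompleteStateError(missing)
    return DerivedIndices(
        ventilatory_ratio=ventilatory_ratio(state.Ve, state.PCO2, state.Vt, state.PBW, mode),
        pf_ratio=pf_ratio(state.PO2, state.FiO2),
        ltvv=ltvv(state.Vt, state.PBW),
        timestamp=state.timestamp,
    )


def evaluate_alerts(
    state: VentilationState,
    vitals: Optional[VitalSample] = None,
    thresholds: Optional[AlertThresholds] = None,
    patient_id: str = "",
) -> list[Alert]:
    """One alert per violated safety rule; empty list iff all rules are safe.

    Ventilation rules (strict violations): LTVV > ``ltvv_max``,
    P/F < ``pf_min``, FiO2 >= ``fio2_max``.  When ``vitals`` are given, each
    vital outside its configured normal range adds a VITAL_OUT_OF_RANGE alert.
    """
    th = thresholds or AlertThresholds()
    indices = derive_indices(state)
    ts = state.timestamp
    alerts: list[Alert] = []
    if indices.ltvv > th.ltvv_max:
        alerts.append(Alert("LTVV_HIGH", indices.ltvv, th.ltvv_max, "above", ts, patient_id, "LTVV"))
    if indices.pf_ratio < th.pf_min:
        alerts.append(Alert("PF_LOW", indices.pf_ratio, th.pf_min, "below", ts, patient_id, "PF"))
    if state.FiO2 >= th.fio2_max:
        alerts.append(Alert("FIO2_HIGH", state.FiO2, th.fio2_max, "above", ts, patient_id, "FiO2"))
    if vitals is not None:
        for name, (lo, hi) in th.vital_ranges.items():
            value = getattr(vitals, name, None)
            if value is None:
                continue
            if value < lo:
                alerts.append(Alert("VITAL_OUT_OF_RANGE", value, lo, "below", ts, patient_id, name))
            elif value > hi:
                alerts.append(Alert("VITAL_OUT_OF_RANGE", value, hi, "above", ts, patient_id, name))
    return alerts


# ---------------------------------------------------------------------------
# Data-level fusion: observations + profile -> per-patient snapshot
# ---------------------------------------------------------------------------


@dataclass
class PatientState:
    """Fused per-patient snapshot with per-field provenance."""

    patient_id: str
    profile: PatientProfile
    ventilation: VentilationState
    vitals: Optional[VitalSample]
    as_of: datetime
    provenance: dict = field(default_factory=dict)


_VENT_FIELDS = ("Vt", "Ve", "FiO2", "PCO2", "PO2")
_VITAL_FIELDS = ("HR", "BP_SYS", "BP_DIA", "RR", "SpO2")


def fuse_patient_state(
    observations: Iterable[ObservationRecord],
    profile: PatientProfile,
    window: timedelta,
    at_time: Optional[datetime] = None,
    code_registry: Optional[CodeRegistry] = None,
) -> PatientState:
    """Latest-value-within-window fusion of observations into one snapshot.

    For each canonical parameter the most recent component at or before
    ``at_time`` (default: the newest observation time) and within ``window``
    wins.  PBW is computed from the profile.  FiO2 reported in percent is
    normalized to a fraction.  Provenance records, per fused field, the
    source observation's index and timestamp.  Raises
    :class:`IncompleteStateError` when a field required for the ventilation
    indices has no observation inside the window.
    """
    if window <= timedelta(0):
        raise DomainError(f"window must be positive, got {window}")
    registry = code_registry or default_code_registry()
    obs = sorted(observations, key=lambda r: r.effective_time)
    if not obs:
        raise IncompleteStateError(list(_VENT_FIELDS))
    as_of = at_time or obs[-1].effective_time
    horizon = as_of - window

    latest: dict[str, tuple[datetime, float, int, str]] = {}
    for idx, record in enumerate(obs):
        t = record.effective_time
        if t > as_of or t <= horizon:
            continue
        for comp in record.components:
            try:
                name = registry.name_for_code(comp.code)
            except KeyError:
                continue
            if not isinstance(comp.value, (int, float)) or isinstance(comp.value, bool):
                continue
            if name not in latest or t >= latest[name][0]:
                latest[name] = (t, float(comp.value), idx, comp.unit or "")

    def take(name: str):
        if name not in latest:
            return None
        _, value, _, unit = latest[name]
        if name == "FiO2" and (unit == "%" or value > 1):
            value = value / 100.0
        return value

    missing = [f for f in _VENT_FIELDS if take(f) is None]
    if missing:
        raise IncompleteStateError(missing)

    ventilation = VentilationState(
        Vt=take("Vt"),
        Ve=take("Ve"),
        FiO2=take("FiO2"),
        PCO2=take("PCO2"),
        PO2=take("PO2"),
        PBW=pbw(profile.sex, profile.height_cm),
        timestamp=as_of,
    )
    vital_values = {f: take(f) for f in _VITAL_FIELDS}
    vitals = (
        VitalSample(**vital_values) if any(v is not None for v in vital_values.values()) else None
    )
    provenance = {
        name: {"observation_index": idx, "observed_at": t.isoformat()}
        for name, (t, _, idx, _) in latest.items()
    }
    provenance["PBW"] = {"source": "profile", "sex": profile.sex, "height_cm": profile.height_cm}
    return PatientState(
        patient_id=profile.patient_id,
        profile=profile,
        ventilation=ventilation,
        vitals=vitals,
        as_of=as_of,
        provenance=provenance,
    )
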