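"""Synthetic cohorts, device-message streams, ARDS tables, worked-case data.

Everything the test bench consumes is generated here, reproducibly under a
seed:

* :func:`generate_cohort` — patient profiles with sex-specific height
  distributions and ward-zone mix.
* :func:`generate_streams` — a multi-dialect raw-message corpus whose
  per-category byte rates preserve the reference deployment's ratios
  (29.7 : 26.1 : 2.32 : 0.344 : 7.2, patient monitors : ventilators :
  hemodynamics : infusion pumps : hematology), scaled down by a recorded
  factor so a desk run stays in kilobytes.  Patient monitors emit HL7 v2,
  infusion pumps emit JSON, the rest emit the proprietary code:value
  dialect; every message parses with the shipped device-feature registry.
* :func:`generate_ards_dataset` — a labeled ventilation feature table.
  The label mechanism is a two-component Gaussian model on a latent P/F
  ratio: class-conditional means separated by ``effect_size`` mmHg with
  within-class spread ``CLASS_PF_SD``.  This is *exactly* a logistic model
  on the latent P/F with coefficient ``-effect_size / CLASS_PF_SD**2``,
  so the mechanism is recoverable by logistic regression, and the
  Bayes-optimal AUC given the noisy observed P/F has the closed form
  ``Phi(effect / sqrt(2 * (CLASS_PF_SD^2 + noise_sd^2)))``.  The label is a
  statistical stand-in (roughly Berlin-like: low oxygenation drives the
  class), not a clinical adjudication.
* :func:`generate_worked_case` — a fixed, seedless two-point trajectory of
  an ARDS admission: severe initial state (tidal volume 600 mL at 60 kg
  predicted body weight, PO2 164 mmHg on 100% oxygen) that triggers all
  three ventilation alerts, then a protective state six hours later
  (LTVV 6.1 mL/kg, P/F 320, FiO2 0.35) that triggers none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .clinical_indices import PatientProfile, VentilationState, WARD_ZONES
from .fhir_model import Device, ObservationComponent, ObservationRecord, make_observation
from .protocol_translation import RawMessage

__all__ = [
    "CohortSpec",
    "StreamSpec",
    "ArdsSimSpec",
    "WorkedCase",
    "CLASS_PF_SD",
    "REFERENCE_CATEGORY_RATES_MBPS",
    "generate_cohort",
    "generate_streams",
    "generate_ards_dataset",
    "bayes_optimal_auc",
    "label_model_coefficient",
    "generate_worked_case",
]

#: Printed per-category stream rates (Mbps) of the reference deployment;
#: generate_streams reproduces these *ratios* at desk scale.
REFERENCE_CATEGORY_RATES_MBPS = {
    "patient_monitor": 29.7,
    "ventilator": 26.1,
    "hemodynamics": 2.32,
    "infusion_pump": 0.344,
    "hematology": 7.2,
}

#: Reference unit counts, scaled down 10x by default for desk runs.
REFERENCE_UNIT_COUNTS = {
    "patient_monitor": 470,
    "ventilator": 180,
    "hemodynamics": 20,
    "infusion_pump": 500,
    "hematology": 30,
}

#: Within-class spread of the latent P/F ratio (mmHg) in the ARDS generator.
CLASS_PF_SD = 45.0
#: Grand mean of the latent P/F ratio (mmHg); class means sit at +-effect/2.
CLASS_PF_CENTER = 255.0


@dataclass(frozen=True)
class CohortSpec:
    n: int = 50
    sex_ratio: float = 0.5  # male fraction
    height_mean: dict = field(
        default_factory=lambda: {"male": 171.0, "female": 158.0}
    )
    height_sd: float = 7.0
    zone_mix: dict = field(
        default_factory=lambda: {
            "negative_pressure": 0.2,
            "contact_isolation": 0.2,
            "regular": 0.6,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        if set(self.zone_mix) - set(WARD_ZONES):
            raise ValueError(f"unknown ward zones in mix: {self.zone_mix}")


def generate_cohort(spec: CohortSpec) -> list[PatientProfile]:
    """Reproducible patient cohort; heights truncated to the 120-230 cm
    validity range of the predicted-body-weight formula."""
    rng = np.random.default_rng(spec.seed)
    zones = list(spec.zone_mix)
    zone_p = np.array([spec.zone_mix[z] for z in zones], dtype=float)
    zone_p = zone_p / zone_p.sum()
    cohort = []
    for i in range(spec.n):
        sex = "male" if rng.random() < spec.sex_ratio else "female"
        height = float(np.clip(rng.normal(spec.height_mean[sex], spec.height_sd), 120, 230))
        cohort.append(
            PatientProfile(
                patient_id=f"P{i + 1:04d}",
                sex=sex,
                height_cm=round(height, 1),
                bed=f"BED{i + 1:02d}",
                ward_zone=zones[int(rng.choice(len(zones), p=zone_p))],
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Device-message streams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StreamSpec:
    """Desk-scale stream workload preserving the reference category ratios.

    ``bytes_per_mbps`` is the scale factor: each category's payload byte
    budget is its printed rate in Mbps times this factor.  The factor is
    recorded in the manifest so the scaling is auditable.
    """

    duration_s: float = 60.0
    bytes_per_mbps: float = 20_000.0
    unit_scale: float = 0.1  # fraction of the reference device counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.bytes_per_mbps <= 0 or not 0 < self.unit_scale <= 1:
            raise ValueError("stream spec parameters must be positive")


_DIALECT_BY_CATEGORY = {
    "patient_monitor": "hl7v2",
    "ventilator": "proprietary",
    "hemodynamics": "proprietary",
    "hematology": "proprietary",
    "infusion_pump": "json",
}


def _hl7_monitor_payload(rng: np.random.Generator, device_id: str, t: datetime) -> str:
    hr = int(np.clip(rng.normal(82, 12), 30, 180))
    spo2 = int(np.clip(rng.normal(96, 2), 80, 100))
    rr = int(np.clip(rng.normal(16, 3), 6, 40))
    sys_bp = int(np.clip(rng.normal(118, 14), 70, 220))
    dia_bp = int(np.clip(rng.normal(74, 10), 40, 140))
    ts = t.strftime("%Y%m%d%H%M%S")
    segments = [
        f"MSH|^~\\&|{device_id}|ICU|RICU|CMD|{ts}||ORU^R01|{device_id}-{ts}|P|2.3",
        f"OBX|1|NM|HR^Heart Rate||{hr}|{{beats}}/min|||||F",
        f"OBX|2|NM|SPO2^Pulse Oximetry||{spo2}|%|||||F",
        f"OBX|3|NM|RR^Respiratory Rate||{rr}|{{breaths}}/min|||||F",
        f"OBX|4|NM|NBPS^NIBP Systolic||{sys_bp}|mm[Hg]|||||F",
        f"OBX|5|NM|NBPD^NIBP Diastolic||{dia_bp}|mm[Hg]|||||F",
    ]
    return "\r".join(segments)


def _ventilator_payload(rng: np.random.Generator) -> str:
    vt = round(float(np.clip(rng.normal(450, 50), 200, 800)), 1)
    ve = round(float(np.clip(rng.normal(8.5, 1.5), 3, 20)), 2)
    fio2 = round(float(np.clip(rng.normal(50, 15), 21, 100)), 1)
    return f"VT:{vt}|VE:{ve}|FIO2:{fio2}"


def _hemodynamics_payload(rng: np.random.Generator) -> str:
    sao2 = round(float(np.clip(rng.normal(96, 2.5), 70, 100)), 1)
    co = round(float(np.clip(rng.normal(5.0, 1.0), 2, 12)), 2)
    sv = round(float(np.clip(rng.normal(70, 12), 30, 150)), 1)
    return f"SAO2:{sao2}|CO:{co}|SV:{sv}"


def _hematology_payload(rng: np.random.Generator) -> str:
    wbc = round(float(np.clip(rng.normal(9.5, 3.5), 1, 40)), 2)
    rbc = round(float(np.clip(rng.normal(4.4, 0.6), 2, 7)), 2)
    hgb = round(float(np.clip(rng.normal(12.5, 1.8), 5, 20)), 1)
    plt = round(float(np.clip(rng.normal(230, 70), 20, 800)), 0)
    po2 = round(float(np.clip(rng.normal(95, 25), 30, 500)), 1)
    pco2 = round(float(np.clip(rng.normal(42, 7), 15, 110)), 1)
    return f"WBC:{wbc}|RBC:{rbc}|HGB:{hgb}|PLT:{plt}|PO2:{po2}|PCO2:{pco2}"


def _infusion_payload(rng: np.random.Generator, t: datetime) -> str:
    rate = round(float(np.clip(rng.normal(85, 40), 1, 1200)), 1)
    return json.dumps(
        {"rate": rate, "unit": "mL/h", "time": t.isoformat()}, separators=(",", ":")
    )


def generate_streams(
    cohort: list[PatientProfile],
    spec: Optional[StreamSpec] = None,
    start: Optional[datetime] = None,
) -> tuple[list[RawMessage], dict]:
    """Raw-message corpus whose per-category byte rates preserve the
    reference ratios; returns ``(messages, manifest)``.

    Patient monitors speak HL7 v2, infusion pumps JSON, and ventilators,
    hemodynamics monitors and hematology analyzers the proprietary dialect.
    Messages are evenly spaced per category over the horizon and stop once
    the category's byte budget is met.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    spec = spec or StreamSpec()
    start = start or datetime(2024, 4, 14, 21, 0, tzinfo=timezone.utc)
    rng = np.random.default_rng(spec.seed)
    messages: list[RawMessage] = []
    byte_counts: dict[str, int] = {}
    for category, rate_mbps in REFERENCE_CATEGORY_RATES_MBPS.items():
        dialect = _DIALECT_BY_CATEGORY[category]
        n_devices = max(1, round(REFERENCE_UNIT_COUNTS[category] * spec.unit_scale))
        budget = rate_mbps * spec.bytes_per_mbps
        emitted = 0
        produced = []
        # Probe a first payload to bound the count, then emit until budget.
        i = 0
        while True:
            t = start + timedelta(seconds=(i * 0.5) % spec.duration_s)
            device_id = f"{category}-{i % n_devices:03d}"
            patient = cohort[i % len(cohort)]
            if category == "patient_monitor":
                payload = _hl7_monitor_payload(rng, device_id, t)
            elif category == "ventilator":
                payload = _ventilator_payload(rng)
            elif category == "hemodynamics":
                payload = _hemodynamics_payload(rng)
            elif category == "hematology":
                payload = _hematology_payload(rng)
            else:
                payload = _infusion_payload(rng, t)
            size = len(payload.encode())
            if emitted + size > budget:
                break
            emitted += size
            produced.append(
                RawMessage(
                    category=category,
                    dialect=dialect,
                    payload=payload,
                    received_time=t,
                    source_device_id=device_id,
                    patient_id=patient.patient_id,
                    location=patient.bed,
                )
            )
            i += 1
        byte_counts[category] = emitted
        messages.extend(produced)
    # Interleave chronologically for downstream realism.
    messages.sort(key=lambda m: (m.received_time, m.category, m.source_device_id))
    manifest = {
        "seed": spec.seed,
        "duration_s": spec.duration_s,
        "bytes_per_mbps": spec.bytes_per_mbps,
        "unit_scale": spec.unit_scale,
        "reference_rates_mbps": dict(REFERENCE_CATEGORY_RATES_MBPS),
        "byte_counts": byte_counts,
        "message_counts": {
            c: sum(1 for m in messages if m.category == c)
            for c in REFERENCE_CATEGORY_RATES_MBPS
        },
    }
    return messages, manifest


# ---------------------------------------------------------------------------
# ARDS feature tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArdsSimSpec:
    """Conditions of the synthetic ARDS classification problem.

    ``effect_size`` is the mean latent-P/F shift between classes (mmHg);
    ``noise_sd`` the measurement noise on the observed oxygenation index
    (mmHg of P/F, applied before scaling PO2 by FiO2).
    """

    n: int = 2000
    prevalence: float = 0.3
    effect_size: float = 150.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect size and noise sd must be >= 0")


def label_model_coefficient(spec: ArdsSimSpec) -> float:
    """Logistic coefficient of the label mechanism on the latent P/F.

    The equal-variance two-Gaussian generative model implies
    ``P(ARDS | pf) = sigmoid(b0 + b1 * pf)`` with exactly
    ``b1 = -effect_size / CLASS_PF_SD**2``.
    """
    return -spec.effect_size / CLASS_PF_SD**2


def bayes_optimal_auc(spec: ArdsSimSpec) -> float:
    """Closed-form AUC of the optimal classifier given the observed P/F:
    ``Phi(effect / sqrt(2 * (CLASS_PF_SD^2 + noise_sd^2)))``."""
    return float(
        norm.cdf(spec.effect_size / np.sqrt(2.0 * (CLASS_PF_SD**2 + spec.noise_sd**2)))
    )


def generate_ards_dataset(spec: ArdsSimSpec, include_latent: bool = False) -> pd.DataFrame:
    """Labeled ventilation feature table with planted oxygenation signal.

    Columns: FiO2 (fraction), PCO2, PO2 (mmHg), Ve (L/min), Vt (mL),
    height (cm), sex, label (1 = ARDS).  ``include_latent`` adds the latent
    noiseless P/F column ``pf_latent`` for mechanism-recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    label = (rng.random(n) < spec.prevalence).astype(int)
    class_mean = np.where(
        label == 1,
        CLASS_PF_CENTER - spec.effect_size / 2.0,
        CLASS_PF_CENTER + spec.effect_size / 2.0,
    )
    pf_latent = class_mean + rng.normal(0.0, CLASS_PF_SD, n)
    pf_latent = np.clip(pf_latent, 30.0, None)
    fio2 = rng.uniform(0.4, 1.0, n)
    pf_observed = pf_latent + rng.normal(0.0, spec.noise_sd, n)
    po2 = np.clip(pf_observed, 20.0, None) * fio2
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    height = np.where(
        sex == "male", rng.normal(171.0, 7.0, n), rng.normal(158.0, 7.0, n)
    )
    table = pd.DataFrame(
        {
            "FiO2": np.round(fio2, 3),
            "PCO2": np.round(np.clip(rng.normal(45.0, 8.0, n), 15.0, None), 1),
            "PO2": np.round(po2, 1),
            "Ve": np.round(np.clip(rng.normal(9.0, 2.0, n), 2.0, None), 2),
            "Vt": np.round(np.clip(rng.normal(450.0, 60.0, n), 150.0, None), 0),
            "height": np.round(np.clip(height, 120.0, 230.0), 1),
            "sex": sex,
            "label": label,
        }
    )
    if include_latent:
        table["pf_latent"] = pf_latent
    return table


# ---------------------------------------------------------------------------
# Worked ARDS admission trajectory
# ---------------------------------------------------------------------------


@dataclass
class WorkedCase:
    profile: PatientProfile
    states: list[VentilationState]
    observations: list[ObservationRecord]


def generate_worked_case() -> WorkedCase:
    """Fixed (seedless) two-point ARDS trajectory.

    At admission (14 April, 21:20 UTC) the ventilation state is constructed
    from tidal volume 600 mL, predicted body weight 60 kg, PO2 164 mmHg and
    FiO2 1.0, so the derived indices are exactly LTVV 10.0 mL/kg, P/F 164
    mmHg, FiO2 1.0 — violating all three safety rules.  Six hours later
    (15 April, 03:30 UTC) tidal volume is 366 mL and oxygenation has
    improved (PO2 112 at FiO2 0.35, P/F 320), so LTVV is exactly 6.1 and no
    rule is violated.  The inputs are reverse-engineered from the target
    indices; only the derived values are externally meaningful.
    """
    profile = PatientProfile(
        patient_id="P0001",
        sex="male",
        height_cm=163.4,  # Devine PBW ~= 60 kg; states carry PBW=60 exactly
        bed="BED07",
        ward_zone="negative_pressure",
    )
    t0 = datetime(2024, 4, 14, 21, 20, tzinfo=timezone.utc)
    t1 = datetime(2024, 4, 15, 3, 30, tzinfo=timezone.utc)
    states = [
        VentilationState(Vt=600.0, Ve=12.0, FiO2=1.0, PCO2=55.0, PO2=164.0, PBW=60.0, timestamp=t0),
        VentilationState(Vt=366.0, Ve=8.0, FiO2=0.35, PCO2=42.0, PO2=112.0, PBW=60.0, timestamp=t1),
    ]
    observations = []
    for state in states:
        components = [
            ObservationComponent("76222-4", "Tidal volume", state.Vt, "mL"),
            ObservationComponent("20139-2", "Exhaled minute volume", state.Ve, "L/min"),
            ObservationComponent("3150-0", "Inhaled oxygen concentration", state.FiO2 * 100.0, "%"),
        ]
        observations.append(
            make_observation(
                "ventilator", profile.patient_id, state.timestamp,
                Device("ventilator", profile.bed), components,
            )
        )
        observations.append(
            make_observation(
                "laboratory", profile.patient_id, state.timestamp,
                Device("hematology", profile.bed),
                [
                    ObservationComponent("2703-1", "PO2", state.PO2, "mm[Hg]"),
                    ObservationComponent("2019-8", "PCO2", state.PCO2, "mm[Hg]"),
                ],
            )
        )
    return WorkedCase(profile=profile, states=states, observations=observations)
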