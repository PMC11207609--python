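"""Ventilation indices, predicted body weight, alerts, patient-state fusion."""

from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings, strategies as st

from icufusion import clinical_indices as ci
from icufusion.fhir_model import Device, ObservationComponent, make_observation

UTC = timezone.utc
T0 = datetime(2024, 4, 14, 21, 20, tzinfo=UTC)


class TestPbw:
    @pytest.mark.parametrize(
        "sex,height,expected",
        [
            ("male", 152.4, 50.0),
            ("female", 152.4, 45.5),
            ("male", 170.0, 66.016),
            ("female", 170.0, 61.516),
        ],
    )
    def test_devine_formula(self, sex, height, expected):
        assert ci.pbw(sex, height) == pytest.approx(expected, abs=1e-9)

    def test_below_anchor_floors_at_base_weight(self):
        assert ci.pbw("male", 140.0) == 50.0
        assert ci.pbw("female", 140.0) == 45.5

    def test_invalid_inputs(self):
        with pytest.raises(ci.DomainError):
            ci.pbw("other", 170.0)
        with pytest.raises(ci.DomainError):
            ci.pbw("male", 110.0)


class TestVentilatoryRatio:
    def test_reference_value(self):
        # (10 * 40 * 450) / (100 * 37.5 * 60) = 0.8
        assert ci.ventilatory_ratio(10, 40, 450, 60) == pytest.approx(0.8)

    def test_doubling_pbw_halves_result(self):
        base = ci.ventilatory_ratio(10, 40, 450, 60)
        assert ci.ventilatory_ratio(10, 40, 450, 120) == pytest.approx(base / 2)

    def test_standard_mode_uses_ml_per_min_without_vt(self):
        # (10 L/min -> 10000 mL/min) * 40 / (100 * 37.5 * 60)
        assert ci.ventilatory_ratio(10, 40, 450, 60, mode="standard") == pytest.approx(
            10_000 * 40 / (100 * 37.5 * 60)
        )

    def test_nonpositive_input_raises(self):
        with pytest.raises(ci.DomainError):
            ci.ventilatory_ratio(10, 40, 450, 0)


class TestPfRatioAndLtvv:
    def test_pf_values(self):
        assert ci.pf_ratio(164, 1.0) == 164
        assert ci.pf_ratio(150, 0.5) == 300

    def test_fio2_domain(self):
        with pytest.raises(ci.DomainError):
            ci.pf_ratio(100, 0)
        with pytest.raises(ci.DomainError):
            ci.pf_ratio(100, 50)  # percent given where a fraction is required

    @pytest.mark.parametrize("vt,pbw,expected", [(480, 60, 8.0), (600, 60, 10.0), (366, 60, 6.1)])
    def test_ltvv_values(self, vt, pbw, expected):
        assert ci.ltvv(vt, pbw) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        vt=st.floats(100, 1000),
        pbw=st.floats(35, 120),
        k=st.floats(0.1, 10),
        po2=st.floats(40, 600),
        fio2=st.floats(0.21, 1.0),
    )
    def test_homogeneity(self, vt, pbw, k, po2, fio2):
        assert ci.ltvv(k * vt, k * pbw) == pytest.approx(ci.ltvv(vt, pbw))
        assert ci.pf_ratio(k * po2, fio2) == pytest.approx(k * ci.pf_ratio(po2, fio2))


def vent_state(ltvv_value=10.0, pf=164.0, fio2=1.0, pbw=60.0, **kw):
    return ci.VentilationState(
        Vt=ltvv_value * pbw,
        Ve=kw.get("Ve", 9.0),
        FiO2=fio2,
        PCO2=kw.get("PCO2", 45.0),
        PO2=pf * fio2,
        PBW=pbw,
        timestamp=T0,
    )


class TestAlerts:
    def test_worked_severe_state_fires_all_three(self):
        alerts = ci.evaluate_alerts(vent_state(10.0, 164.0, 1.0))
        assert sorted(a.kind for a in alerts) == ["FIO2_HIGH", "LTVV_HIGH", "PF_LOW"]

    def test_safe_state_fires_none(self):
        assert ci.evaluate_alerts(vent_state(6.1, 320.0, 0.35)) == []

    def test_boundaries_are_safe(self):
        # LTVV == 8 and P/F == 300 are safe; FiO2 == 0.4 violates (>= rule).
        assert ci.evaluate_alerts(vent_state(8.0, 300.0, 0.39)) == []
        alerts = ci.evaluate_alerts(vent_state(8.0, 300.0, 0.4))
        assert [a.kind for a in alerts] == ["FIO2_HIGH"]

    @pytest.mark.parametrize("ltvv_value", [7.9, 8.0, 8.1])
    @pytest.mark.parametrize("pf", [299.0, 300.0, 301.0])
    @pytest.mark.parametrize("fio2", [0.39, 0.4, 0.41])
    def test_alert_iff_printed_inequality_violated(self, ltvv_value, pf, fio2):
        """Exhaustive grid straddling all three thresholds."""
        kinds = {a.kind for a in ci.evaluate_alerts(vent_state(ltvv_value, pf, fio2))}
        assert ("LTVV_HIGH" in kinds) == (ltvv_value > 8)
        assert ("PF_LOW" in kinds) == (pf < 300)
        assert ("FIO2_HIGH" in kinds) == (fio2 >= 0.4)

    def test_vital_out_of_range(self):
        vitals = ci.VitalSample(HR=130, SpO2=90, RR=16, BP_SYS=100)
        alerts = ci.evaluate_alerts(vent_state(6.0, 350.0, 0.3), vitals)
        assert sorted((a.kind, a.parameter) for a in alerts) == [
            ("VITAL_OUT_OF_RANGE", "HR"),
            ("VITAL_OUT_OF_RANGE", "SpO2"),
        ]


def obs(code, value, unit, t, name="x"):
    return make_observation(
        "test", "P001", t, Device("dev", "BED01"),
        [ObservationComponent(code, name, value, unit)],
    )


@pytest.fixture()
def profile():
    return ci.PatientProfile("P001", "male", 170.0, "BED01", "regular")


class TestFusion:
    def vent_observations(self, t):
        return [
            obs("76222-4", 450.0, "mL", t),
            obs("20139-2", 8.5, "L/min", t),
            obs("3150-0", 50.0, "%", t),  # percent normalizes to 0.5
            obs("2019-8", 42.0, "mm[Hg]", t + timedelta(minutes=1)),
            obs("2703-1", 95.0, "mm[Hg]", t + timedelta(minutes=1)),
        ]

    def test_complete_state_from_ventilator_and_blood_gas(self, profile, code_registry):
        state = ci.fuse_patient_state(
            self.vent_observations(T0), profile, timedelta(hours=2), code_registry=code_registry
        )
        assert state.ventilation.FiO2 == pytest.approx(0.5)
        assert state.ventilation.PBW == pytest.approx(66.016)
        assert state.provenance["Vt"]["observation_index"] == 0

    def test_last_write_wins(self, profile, code_registry):
        early = obs("8867-4", 70, "{beats}/min", T0)
        late = obs("8867-4", 95, "{beats}/min", T0 + timedelta(minutes=30))
        state = ci.fuse_patient_state(
            self.vent_observations(T0) + [early, late],
            profile,
            timedelta(hours=2),
            code_registry=code_registry,
        )
        assert state.vitals.HR == 95

    def test_stale_required_field_raises_incomplete(self, profile, code_registry):
        observations = self.vent_observations(T0)
        # Push the blood gas out of the fusion window.
        observations[-1] = obs("2703-1", 95.0, "mm[Hg]", T0 - timedelta(hours=5))
        with pytest.raises(ci.IncompleteStateError) as exc:
            ci.fuse_patient_state(
                observations, profile, timedelta(hours=2), code_registry=code_registry
            )
        assert "PO2" in exc.value.missing

    def test_fusion_is_idempotent(self, profile, code_registry):
        observations = self.vent_observations(T0)
        a = ci.fuse_patient_state(observations, profile, timedelta(hours=2),
                                  code_registry=code_registry)
        b = ci.fuse_patient_state(observations, profile, timedelta(hours=2),
                                  code_registry=code_registry)
        assert a == b
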