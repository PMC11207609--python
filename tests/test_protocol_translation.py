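"""Device-feature management, parser compilation, dialect parsing, translation."""

from datetime import datetime, timezone

import pytest

from icufusion import protocol_translation as pt
from icufusion.fhir_model import ValidationError

UTC = timezone.utc
T0 = datetime(2024, 4, 14, 21, 20, tzinfo=UTC)


def sao2_feature(**overrides):
    fields = dict(
        category="hemodynamics",
        name="SaO2",
        dialect="proprietary",
        field_locator="SAO2",
        value_type="decimal",
        value_range=(0.0, 100.0),
        delimiter="|",
    )
    fields.update(overrides)
    return pt.DeviceFeature(**fields)


def msg(payload, category="hemodynamics", dialect="proprietary", patient="P001"):
    return pt.RawMessage(
        category=category,
        dialect=dialect,
        payload=payload,
        received_time=T0,
        source_device_id="dev-1",
        patient_id=patient,
        location="BED07",
    )


class TestRegistry:
    def test_register_and_retrieve(self):
        registry = pt.DeviceFeatureRegistry()
        registry.register(sao2_feature())
        assert len(registry.features_for("hemodynamics", "proprietary")) == 1

    def test_invalid_range_rejected(self):
        with pytest.raises(ValidationError, match="range"):
            sao2_feature(value_range=(100.0, 0.0))

    def test_proprietary_without_delimiter_rejected(self):
        with pytest.raises(ValidationError, match="delimiter"):
            sao2_feature(delimiter=None)

    def test_reregistration_replaces_with_audit_entry(self):
        registry = pt.DeviceFeatureRegistry()
        registry.register(sao2_feature())
        registry.register(sao2_feature(field_locator="SPO2A"))
        assert len(registry) == 1
        assert len(registry.audit_log) == 1
        assert registry.audit_log[0]["action"] == "replace"

    def test_json_round_trip(self, tmp_path, feature_registry):
        path = tmp_path / "dfm.json"
        feature_registry.to_json(path)
        back = pt.DeviceFeatureRegistry.from_json(path)
        assert sorted(back, key=lambda d: (d.category, d.name)) == sorted(
            feature_registry, key=lambda d: (d.category, d.name)
        )


class TestCompileParser:
    def test_rule_count_matches_registered_features(self, feature_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        assert len(rules.rules) == 3  # SaO2, CO, SV

    def test_unregistered_category_raises(self, feature_registry):
        with pytest.raises(pt.EmptyCategoryError):
            pt.compile_parser("mri", "proprietary", feature_registry)

    def test_recompilation_is_byte_identical(self, feature_registry):
        a = pt.compile_parser("ventilator", "proprietary", feature_registry)
        b = pt.compile_parser("ventilator", "proprietary", feature_registry)
        assert a == b
        assert a.compiled_at == b.compiled_at


class TestParseMessage:
    def test_proprietary_two_features(self, feature_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        result = pt.parse_message(msg("SAO2:97|CO:4.8"), rules)
        assert [(v.name, v.value) for v in result.values] == [("SaO2", 97.0), ("CO", 4.8)]
        assert result.residue == []

    def test_hl7_obx_heart_rate(self, feature_registry):
        payload = (
            "MSH|^~\\&|mon|ICU|RICU|CMD|20240414212000||ORU^R01|1|P|2.3\r"
            "OBX|1|NM|HR^Heart Rate||88|{beats}/min|||||F"
        )
        rules = pt.compile_parser("patient_monitor", "hl7v2", feature_registry)
        result = pt.parse_message(msg(payload, "patient_monitor", "hl7v2"), rules)
        assert [(v.name, v.value) for v in result.values] == [("HR", 88)]
        assert result.device_time == datetime(2024, 4, 14, 21, 20, tzinfo=UTC)

    def test_json_key_path(self, feature_registry):
        rules = pt.compile_parser("infusion_pump", "json", feature_registry)
        result = pt.parse_message(
            msg('{"rate":5.0,"unit":"mL/h"}', "infusion_pump", "json"), rules
        )
        assert [(v.name, v.value) for v in result.values] == [("INFUSION_RATE", 5.0)]
        assert result.residue == ["unit"]

    def test_out_of_range_value_flagged_not_dropped(self, feature_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        result = pt.parse_message(msg("SAO2:250"), rules)
        (value,) = result.values
        assert value.value == 250.0
        assert "out_of_range" in value.flags

    def test_unmatched_tokens_reported_as_residue(self, feature_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        result = pt.parse_message(msg("SAO2:97|MYSTERY:1"), rules)
        assert result.residue == ["MYSTERY:1"]

    def test_dialect_mismatch(self, feature_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        with pytest.raises(pt.DialectMismatchError):
            pt.parse_message(msg('{"a":1}', "hemodynamics", "json"), rules)

    def test_undecodable_payload_carries_offset(self, feature_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        with pytest.raises(pt.ParseError):
            pt.parse_message(msg("SAO2:97|GARBAGE-NO-DELIM"), rules)


class TestTranslate:
    def test_sao2_component_coded_2708_6(self, feature_registry, code_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        record = pt.translate(msg("SAO2:97"), rules, code_registry)
        (comp,) = record.components
        assert comp.code == "2708-6"
        assert comp.value == 97.0
        assert record.subject == "P001"

    def test_infusion_pump_json(self, feature_registry, code_registry):
        rules = pt.compile_parser("infusion_pump", "json", feature_registry)
        record = pt.translate(
            msg('{"rate":5,"unit":"mL/h"}', "infusion_pump", "json"), rules, code_registry
        )
        assert record.components[0].value == 5.0
        assert record.code == "infusion"

    def test_no_extractable_features_raises(self, feature_registry, code_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        with pytest.raises(pt.EmptyTranslationError):
            pt.translate(msg("UNKNOWN:1|ALSO:2"), rules, code_registry)

    def test_missing_patient_id_warns_and_uses_unknown(self, feature_registry, code_registry):
        rules = pt.compile_parser("hemodynamics", "proprietary", feature_registry)
        with pytest.warns(UserWarning, match="UNKNOWN"):
            record = pt.translate(msg("SAO2:97", patient=""), rules, code_registry)
        assert record.subject == "UNKNOWN"

    def test_device_time_preferred_over_received_time(self, feature_registry, code_registry):
        payload = (
            "MSH|^~\\&|mon|ICU|RICU|CMD|20240414210000||ORU^R01|1|P|2.3\r"
            "OBX|1|NM|HR^Heart Rate||88|{beats}/min|||||F"
        )
        rules = pt.compile_parser("patient_monitor", "hl7v2", feature_registry)
        record = pt.translate(msg(payload, "patient_monitor", "hl7v2"), rules, code_registry)
        assert record.effective_time == datetime(2024, 4, 14, 21, 0, tzinfo=UTC)

    def test_translation_is_deterministic(self, feature_registry, code_registry):
        rules = pt.compile_parser("ventilator", "proprietary", feature_registry)
        m = msg("VT:450.0|VE:8.5|FIO2:60.0", "ventilator")
        assert pt.translate(m, rules, code_registry) == pt.translate(m, rules, code_registry)


class TestValueConservation:
    def test_zero_loss_over_synthetic_corpus(self, small_corpus, code_registry):
        """Every emitted feature value survives translation bit-identically."""
        messages, rules, _ = small_corpus
        emitted_values = 0
        component_values = 0
        for m in messages:
            r = rules[(m.category, m.dialect)]
            parsed = pt.parse_message(m, r)
            emitted_values += len(parsed.values)
            record = pt.translate(m, r, code_registry)
            component_values += len(record.components)
            assert [c.value for c in record.components] == [v.value for v in parsed.values]
        assert emitted_values == component_values
        assert emitted_values > 0
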