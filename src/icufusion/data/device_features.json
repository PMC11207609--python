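{
  "version": "1",
  "features": [
    {"category": "patient_monitor", "name": "HR", "dialect": "hl7v2", "field_locator": "HR", "value_type": "integer", "value_range": [0, 300]},
    {"category": "patient_monitor", "name": "SpO2", "dialect": "hl7v2", "field_locator": "SPO2", "value_type": "integer", "value_range": [0, 100]},
    {"category": "patient_monitor", "name": "RR", "dialect": "hl7v2", "field_locator": "RR", "value_type": "integer", "value_range": [0, 80]},
    {"category": "patient_monitor", "name": "BP_SYS", "dialect": "hl7v2", "field_locator": "NBPS", "value_type": "integer", "value_range": [0, 350]},
    {"category": "patient_monitor", "name": "BP_DIA", "dialect": "hl7v2", "field_locator": "NBPD", "value_type": "integer", "value_range": [0, 250]},
    {"category": "ventilator", "name": "Vt", "dialect": "proprietary", "field_locator": "VT", "value_type": "decimal", "value_range": [0, 2500], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "ventilator", "name": "Ve", "dialect": "proprietary", "field_locator": "VE", "value_type": "decimal", "value_range": [0, 60], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "ventilator", "name": "FiO2", "dialect": "proprietary", "field_locator": "FIO2", "value_type": "decimal", "value_range": [21, 100], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hemodynamics", "name": "SaO2", "dialect": "proprietary", "field_locator": "SAO2", "value_type": "decimal", "value_range": [0, 100], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hemodynamics", "name": "CO", "dialect": "proprietary", "field_locator": "CO", "value_type": "decimal", "value_range": [0, 25], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hemodynamics", "name": "SV", "dialect": "proprietary", "field_locator": "SV", "value_type": "decimal", "value_range": [0, 250], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hematology", "name": "WBC", "dialect": "proprietary", "field_locator": "WBC", "value_type": "decimal", "value_range": [0, 500], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hematology", "name": "RBC", "dialect": "proprietary", "field_locator": "RBC", "value_type": "decimal", "value_range": [0, 10], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hematology", "name": "HGB", "dialect": "proprietary", "field_locator": "HGB", "value_type": "decimal", "value_range": [0, 25], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hematology", "name": "PLT", "dialect": "proprietary", "field_locator": "PLT", "value_type": "decimal", "value_range": [0, 2000], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hematology", "name": "PO2", "dialect": "proprietary", "field_locator": "PO2", "value_type": "decimal", "value_range": [0, 760], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "hematology", "name": "PCO2", "dialect": "proprietary", "field_locator": "PCO2", "value_type": "decimal", "value_range": [0, 250], "delimiter": "|", "kv_delimiter": ":"},
    {"category": "infusion_pump", "name": "INFUSION_RATE", "dialect": "json", "field_locator": "rate", "value_type": "decimal", "value_range": [0, 1500]}
  ]
}
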