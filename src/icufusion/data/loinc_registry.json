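{
  "version": "1.0",
  "comment": "Canonical parameter name -> LOINC code / UCUM unit / value type. Provenance 'well-known' marks the two codes that are universally printed with these parameters (heart rate, arterial oxygen saturation); 'external-standard' marks best-effort mappings taken from the public LOINC table.",
  "entries": {
    "HR": {"loinc": "8867-4", "unit": "{beats}/min", "value_type": "integer", "display": "Heart rate", "provenance": "well-known"},
    "SaO2": {"loinc": "2708-6", "unit": "%", "value_type": "decimal", "display": "Oxygen saturation in Arterial blood", "provenance": "well-known"},
    "SpO2": {"loinc": "59408-5", "unit": "%", "value_type": "integer", "display": "Oxygen saturation by Pulse oximetry", "provenance": "external-standard"},
    "RR": {"loinc": "9279-1", "unit": "{breaths}/min", "value_type": "integer", "display": "Respiratory rate", "provenance": "external-standard"},
    "BP_SYS": {"loinc": "8480-6", "unit": "mm[Hg]", "value_type": "integer", "display": "Systolic blood pressure", "provenance": "external-standard"},
    "BP_DIA": {"loinc": "8462-4", "unit": "mm[Hg]", "value_type": "integer", "display": "Diastolic blood pressure", "provenance": "external-standard"},
    "Vt": {"loinc": "76222-4", "unit": "mL", "value_type": "decimal", "display": "Tidal volume", "provenance": "external-standard"},
    "Ve": {"loinc": "20139-2", "unit": "L/min", "value_type": "decimal", "display": "Exhaled minute volume", "provenance": "external-standard"},
    "FiO2": {"loinc": "3150-0", "unit": "%", "value_type": "decimal", "display": "Inhaled oxygen concentration", "provenance": "external-standard"},
    "PO2": {"loinc": "2703-1", "unit": "mm[Hg]", "value_type": "decimal", "display": "Oxygen partial pressure in Arterial blood", "provenance": "external-standard"},
    "PCO2": {"loinc": "2019-8", "unit": "mm[Hg]", "value_type": "decimal", "display": "Carbon dioxide partial pressure in Arterial blood", "provenance": "external-standard"},
    "CO": {"loinc": "8741-1", "unit": "L/min", "value_type": "decimal", "display": "Cardiac output", "provenance": "external-standard"},
    "SV": {"loinc": "8769-2", "unit": "mL", "value_type": "decimal", "display": "Stroke volume", "provenance": "external-standard"},
    "WBC": {"loinc": "6690-2", "unit": "10*3/uL", "value_type": "decimal", "display": "Leukocytes in Blood", "provenance": "external-standard"},
    "RBC": {"loinc": "789-8", "unit": "10*6/uL", "value_type": "decimal", "display": "Erythrocytes in Blood", "provenance": "external-standard"},
    "HGB": {"loinc": "718-7", "unit": "g/dL", "value_type": "decimal", "display": "Hemoglobin in Blood", "provenance": "external-standard"},
    "PLT": {"loinc": "777-3", "unit": "10*3/uL", "value_type": "decimal", "display": "Platelets in Blood", "provenance": "external-standard"},
    "INFUSION_RATE": {"loinc": "33162-5", "unit": "mL/h", "value_type": "decimal", "display": "Infusion pump delivery rate", "provenance": "external-standard"}
  }
}
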