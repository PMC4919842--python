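{
  "comment": "Mapping from source-vocabulary semantic-type labels onto the 12 taxonomy semantic types. Labels absent from this table leave a bound concept untyped (with a warning); the mapping is this package's own convention.",
  "map": {
    "Disease or Syndrome": "Disease Disorder",
    "Pathologic Function": "Disease Disorder",
    "Anatomical Abnormality": "Problem",
    "Finding": "Problem",
    "Sign or Symptom": "Sign or Symptom",
    "Pharmacologic Substance": "Medication",
    "Organic Chemical": "Medication",
    "Clinical Drug": "Medication",
    "Body Part, Organ, or Organ Component": "Anatomical Site",
    "Body Location or Region": "Anatomical Site",
    "Laboratory Procedure": "Lab/Test/Measurement",
    "Clinical Attribute": "Vital Sign",
    "Diagnostic Procedure": "Procedure Intervention",
    "Therapeutic or Preventive Procedure": "Procedure Intervention",
    "Health Care Activity": "Encounter",
    "Individual Behavior": "Social Risk Factor"
  }
}
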