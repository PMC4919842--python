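{
  "format": "semschema-registry",
  "version": 1,
  "comment": "Modifier taxonomy: 12 semantic types with their semantic-modifier classes (declared cardinality, closure, seeded values) and the 7 shared-modifier categories with closed value sets. Classes whose declared cardinality exceeds the seeded values are OPEN: the full source value sets are not enumerable here, so OPEN classes accept values beyond the seed while preserving the declared cardinality as metadata.",
  "semantic_types": [
    {
      "name": "Allergy Intolerance",
      "category": "EVENT",
      "classes": [
        {"name": "Allergy/Intolerance Type", "declared_cardinality": 2, "closure": "CLOSED", "values": ["allergy", "intolerance"]},
        {"name": "Allergen", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Severity", "declared_cardinality": 7, "closure": "OPEN", "values": ["mild", "moderate", "severe"]}
      ]
    },
    {
      "name": "Anatomical Site",
      "category": "EVENT",
      "classes": [
        {"name": "Body Side", "declared_cardinality": 3, "closure": "CLOSED", "values": ["right", "left", "bilateral"]},
        {"name": "Body Laterality", "declared_cardinality": 33, "closure": "OPEN", "values": ["dorsal", "medial", "superior"]}
      ]
    },
    {
      "name": "Disease Disorder",
      "category": "EVENT",
      "classes": [
        {"name": "Course", "declared_cardinality": 37, "closure": "OPEN", "values": ["increased", "worsened", "maintained"]},
        {"name": "Severity", "declared_cardinality": 7, "closure": "OPEN", "values": ["mild", "moderate", "severe"]}
      ]
    },
    {
      "name": "Encounter",
      "category": "EVENT",
      "classes": [
        {"name": "From Location", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["home", "ER", "SICU", "nursing home"]},
        {"name": "To Location", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["home", "ER", "SICU", "nursing home"]}
      ]
    },
    {
      "name": "Lab/Test/Measurement",
      "category": "EVENT",
      "classes": [
        {"name": "Abnormal Interpretation", "declared_cardinality": 3, "closure": "CLOSED", "values": ["abnormal", "not abnormal", "very abnormal"]},
        {"name": "Delta Flag", "declared_cardinality": 8, "closure": "OPEN", "values": ["changed", "unchanged", "increased"]},
        {"name": "Lab/Test/Measurement Value", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["500 cc", "100 kg", "12000 WBCs"]},
        {"name": "Ordinal Interpretation", "declared_cardinality": 35, "closure": "OPEN", "values": ["excessive", "high", "low", "positive"]}
      ]
    },
    {
      "name": "Medication",
      "category": "EVENT",
      "classes": [
        {"name": "Medication Form", "declared_cardinality": 27, "closure": "OPEN", "values": ["capsule", "cream", "liquid", "tablet", "pill"]},
        {"name": "Medication Route", "declared_cardinality": 21, "closure": "OPEN", "values": ["inhalation", "intradermal", "oral"]},
        {"name": "Medication Strength", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["500 mg"]},
        {"name": "Status Change", "declared_cardinality": 8, "closure": "OPEN", "values": ["changed", "unchanged", "increased"]},
        {"name": "Dosage", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["250 mg", "16 units"]}
      ]
    },
    {
      "name": "Patient Demographic",
      "category": "PERSON",
      "classes": [
        {"name": "Birth Date", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Death Date", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Age", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Gender", "declared_cardinality": 2, "closure": "OPEN", "values": []},
        {"name": "Race", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "First Name", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Last Name", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Middle Name", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []}
      ]
    },
    {
      "name": "Problem",
      "category": "EVENT",
      "classes": [
        {"name": "Course", "declared_cardinality": 37, "closure": "OPEN", "values": ["increased", "worsened", "maintained"]},
        {"name": "Severity", "declared_cardinality": 7, "closure": "OPEN", "values": ["mild", "moderate", "severe"]}
      ]
    },
    {
      "name": "Procedure Intervention",
      "category": "EVENT",
      "classes": [
        {"name": "Delta Flag", "declared_cardinality": 8, "closure": "OPEN", "values": ["changed", "unchanged", "increased"]},
        {"name": "Procedure Completion", "declared_cardinality": 3, "closure": "CLOSED", "values": ["complete", "incomplete", "N/A"]},
        {"name": "Procedure/Intervention Device", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": []},
        {"name": "Procedure/Intervention Method", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["arthroscopic surgery"]}
      ]
    },
    {
      "name": "Sign or Symptom",
      "category": "EVENT",
      "classes": [
        {"name": "Course", "declared_cardinality": 37, "closure": "OPEN", "values": ["increased", "worsened", "maintained"]},
        {"name": "Severity", "declared_cardinality": 7, "closure": "OPEN", "values": ["mild", "moderate", "severe"]}
      ]
    },
    {
      "name": "Social Risk Factor",
      "category": "EVENT",
      "classes": [
        {"name": "Delta Flag", "declared_cardinality": 8, "closure": "OPEN", "values": ["changed", "unchanged", "increased"]},
        {"name": "Social Risk Qualifier", "declared_cardinality": 6, "closure": "OPEN", "values": ["occasional", "frequent", "social"]},
        {"name": "Social Risk Quantity", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["5 packs", "3 drinks"]},
        {"name": "Social Risk Status", "declared_cardinality": 5, "closure": "OPEN", "values": ["former risk", "current risk"]}
      ]
    },
    {
      "name": "Vital Sign",
      "category": "EVENT",
      "classes": [
        {"name": "Abnormal Interpretation", "declared_cardinality": 3, "closure": "CLOSED", "values": ["abnormal", "not abnormal", "very abnormal"]},
        {"name": "Delta Flag", "declared_cardinality": 8, "closure": "OPEN", "values": ["changed", "unchanged", "increased"]},
        {"name": "Ordinal Interpretation", "declared_cardinality": 37, "closure": "OPEN", "values": ["excessive", "high", "low", "positive"]},
        {"name": "Vital Sign Value", "declared_cardinality": "unlimited", "closure": "UNLIMITED", "values": ["19 bpm", "86 %", "101.4 F"]}
      ]
    }
  ],
  "shared_modifiers": {
    "Certainty": ["Definite Existence", "Definite Negated Existence", "Probable Existence", "Probable Negated Existence"],
    "Experiencer": ["Patient", "Family Member", "Donor Family Member", "Donor Other Member", "Other Member"],
    "Temporality": ["Before", "Before-Overlap", "Overlap", "After"],
    "Contextual Aspect": ["Continues", "Initiates", "Intermittent", "Novel", "Reinitiates", "Terminates"],
    "Contextual Modality": ["Hypothetical", "Conditional"],
    "Degree": ["Little", "Most"],
    "Permanence": ["Finite", "Permanent"]
  }
}
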