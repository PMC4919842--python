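cui	semantic_type
C9000001	Anatomical Abnormality
C9000002	Pathologic Function
C9000003	Pathologic Function
C9000004	Pharmacologic Substance
C9000005	Body Part, Organ, or Organ Component
C9000006	Body Part, Organ, or Organ Component
C9000007	Body Part, Organ, or Organ Component
C9000008	Body Part, Organ, or Organ Component
C9000009	Finding
C9000010	Disease or Syndrome
C9000011	Disease or Syndrome
C9000012	Disease or Syndrome
C9000013	Sign or Symptom
C9000014	Clinical Attribute
C9000015	Sign or Symptom
C9000016	Sign or Symptom
C9000017	Sign or Symptom
C9000018	Disease or Syndrome
C9000019	Disease or Syndrome
C9000020	Pharmacologic Substance
C9000021	Pharmacologic Substance
C9000022	Pharmacologic Substance
C9000023	Pharmacologic Substance
C9000024	Diagnostic Procedure
C9000025	Therapeutic or Preventive Procedure
C9000026	Diagnostic Procedure
C9000027	Laboratory Procedure
C9000028	Laboratory Procedure
C9000029	Clinical Attribute
C9000030	Clinical Attribute
C9000031	Finding
C9000032	Pathologic Function
C9000033	Pathologic Function
C9000034	Individual Behavior
C9000035	Health Care Activity
C9000036	Natural Phenomenon or Process
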