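cui	term	preferred
C9000001	Aneurysm	Y
C9000001	aneurysmal dilatation	N
C9000001	aneurism	N
C9000002	Occlusion	Y
C9000002	occluded	N
C9000002	blockage	N
C9000003	Stenosis	Y
C9000003	narrowing	N
C9000003	stenotic	N
C9000004	Ibuprofen	Y
C9000004	Advil	N
C9000004	Motrin	N
C9000004	Midol	N
C9000005	Internal carotid artery	Y
C9000005	ICA	N
C9000006	Common carotid artery	Y
C9000006	CCA	N
C9000007	External carotid artery	Y
C9000007	ECA	N
C9000008	Vertebral artery	Y
C9000009	Atherosclerotic plaque	Y
C9000009	plaque	N
C9000010	Atherosclerosis	Y
C9000010	atherosclerotic disease	N
C9000011	Pneumonia	Y
C9000011	pneumonitis	N
C9000012	Influenza	Y
C9000012	flu	N
C9000013	Cough	Y
C9000013	tussis	N
C9000014	Body temperature	Y
C9000014	temperature	N
C9000014	temp	N
C9000015	Fever	Y
C9000015	pyrexia	N
C9000015	febrile	N
C9000016	Headache	Y
C9000016	cephalgia	N
C9000017	Chest pain	Y
C9000017	thoracic pain	N
C9000018	Hypertension	Y
C9000018	high blood pressure	N
C9000018	HTN	N
C9000019	Diabetes mellitus	Y
C9000019	DM	N
C9000020	Aspirin	Y
C9000020	acetylsalicylic acid	N
C9000020	ASA	N
C9000021	Acetaminophen	Y
C9000021	Tylenol	N
C9000021	paracetamol	N
C9000022	Warfarin	Y
C9000022	Coumadin	N
C9000023	Amoxicillin	Y
C9000023	Amoxil	N
C9000024	Colonoscopy	Y
C9000025	Carotid endarterectomy	Y
C9000025	CEA	N
C9000026	Ultrasonography	Y
C9000026	ultrasound	N
C9000026	sonogram	N
C9000027	Hemoglobin measurement	Y
C9000027	hemoglobin level	N
C9000028	White blood cell count	Y
C9000028	WBC count	N
C9000029	Blood pressure	Y
C9000029	BP	N
C9000030	Heart rate	Y
C9000030	pulse rate	N
C9000031	Infiltrate	Y
C9000031	pulmonary infiltrate	N
C9000032	Thrombosis	Y
C9000032	thrombus	N
C9000033	Embolism	Y
C9000033	embolus	N
C9000034	Tobacco smoking	Y
C9000034	smoking	N
C9000035	Hospital admission	Y
C9000035	admission to hospital	N
C9000036	Doppler effect	Y
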