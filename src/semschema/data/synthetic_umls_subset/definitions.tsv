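cui	definition
C9000001	Abnormal localized dilatation of a blood vessel wall.
C9000002	Complete obstruction of the lumen of a vessel or hollow organ.
C9000003	Abnormal narrowing of a vessel or other tubular structure.
C9000004	A non-steroidal anti-inflammatory agent with analgesic and antipyretic properties.
C9000005	The artery arising from the common carotid artery that supplies the anterior brain.
C9000010	Thickening and loss of elasticity of arterial walls due to plaque deposition.
C9000011	Inflammatory condition of the lung usually caused by infection.
C9000012	An acute viral respiratory infection.
C9000015	Elevation of body temperature above the normal range.
C9000024	Endoscopic examination of the colon.
C9000026	Imaging of body structures using reflected high-frequency sound waves.
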