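patient_id	dna_events	overexpressed_genes
SL00402		HDAC2,HDAC4,HDAC9
SL00393		HDAC2,HDAC8,RAD23,CTBP2
SL00477		HDAC2,HDAC9,CTBP2
SL00522	ALK:CN-gain	ALK
SL00511		RET
SL00535		PDGFRB,DDR2
SL00545		HDAC2
SL00558		HDAC2
SL00575		HDAC2
SL00581		HDAC2,HDAC9
SL00586		HDAC2,HDAC9
SL00587		HDAC2,HDAC9
SL00589		HDAC2,HDAC9
SL00605	ALK:SNV:F1174L	ALK
SL00608		HDAC2,HDAC8,CTBP2
SL00625		HDAC2,HDAC9
SL00650		HDAC2
SL00653		HDAC2
SL00680		HDAC2
SL00720		HDAC2
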