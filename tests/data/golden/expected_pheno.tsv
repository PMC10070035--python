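eid	CG_COPD	CG_ASTHMA	CMP_RESP	SODIUM	LDL_STATIN_DELTA	CMP_RESP_ONSET
P1	1	NA	1	140	NA	60
P2	0	0	1	NA	NA	56.72005476
P3	NA	1	NA	136	NA	NA
P4	0	0	0	NA	-1.4	NA
P5	0	0	NA	132	NA	NA
P6	1	NA	1	NA	NA	47.6605065
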