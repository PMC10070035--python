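vocab	pattern	match_mode	group_id	group_label	exclusion_groups	category
ICD10	J44	prefix	CG_COPD	COPD	CG_ASTHMA	respiratory
ICD10	J45	prefix	CG_ASTHMA	Asthma	CG_COPD	respiratory
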