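eid	source	vocab	code	date	value	unit
P1	hospital	ICD10	J44.1	2010-01-01	NA	NA
P1	hospital	ICD10	J44.9	2011-05-01	NA	NA
P2	hospital	ICD10	J44.1	2012-03-04	NA	NA
P2	prescription	CUSTOM	RX_TIO	2014-01-01	NA	NA
P2	prescription	CUSTOM	RX_TIO	2014-06-01	NA	NA
P3	hospital	ICD10	J45.0	2009-02-02	NA	NA
P3	hospital	ICD10	J45.9	2009-02-02	NA	NA
P3	hospital	ICD10	J45.1	2010-06-06	NA	NA
P5	hospital	ICD10	J45.9	2015-01-01	NA	NA
P6	hospital	ICD10	J44.3	2013-01-01	NA	NA
P6	hospital	ICD10	J44.3	2013-02-01	NA	NA
P1	primary_care	CUSTOM	NA_BLOOD	2005-01-01	138	mmol/L
P1	primary_care	CUSTOM	NA_BLOOD	2006-01-01	142	mmol/L
P2	primary_care	CUSTOM	NA_BLOOD	2010-01-01	140	mmol/L
P3	primary_care	CUSTOM	NA_BLOOD	2008-01-01	135	mmol/L
P3	primary_care	CUSTOM	NA_BLOOD	2009-01-01	137	mmol/L
P3	primary_care	CUSTOM	NA_BLOOD	2010-01-01	9999	mmol/L
P5	primary_care	CUSTOM	NA_BLOOD	2011-01-01	130	mmol/L
P5	primary_care	CUSTOM	NA_BLOOD	2012-01-01	132	mmol/L
P5	primary_care	CUSTOM	NA_BLOOD	2013-01-01	134	mmol/L
P4	prescription	CUSTOM	RX_STATIN	2010-06-01	NA	NA
P4	primary_care	CUSTOM	LDL	2010-01-10	5.0	mmol/L
P4	primary_care	CUSTOM	LDL	2010-03-01	5.4	mmol/L
P4	primary_care	CUSTOM	LDL	2010-06-01	99	mmol/L
P4	primary_care	CUSTOM	LDL	2010-09-01	4.0	mmol/L
P4	primary_care	CUSTOM	LDL	2011-01-01	3.6	mmol/L
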