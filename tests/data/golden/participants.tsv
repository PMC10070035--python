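eid	sex	birth_date
P1	F	1950-01-01
P2	M	1955-06-15
P3	F	1960-03-10
P4	M	1948-12-01
P5	F	1970-07-20
P6	M	1965-05-05
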