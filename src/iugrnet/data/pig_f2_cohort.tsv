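fetus_id	dam	sex	weight_g	group
E352	1	male	175	AGA
E363	1	male	182	AGA
E370	2	female	154.4	AGA
E272	3	female	183	AGA
E283	3	male	186.6	AGA
E297	4	male	194.4	AGA
E324	5	male	196.6	AGA
E327	5	male	192.8	AGA
E307	6	female	155.5	AGA
E313	6	male	157.5	AGA
E377	7	female	163.1	AGA
E340	8	female	170.6	AGA
E355	1	male	106.2	IUGR
E360	1	male	94.2	IUGR
E376	2	female	125.9	IUGR
E274	3	male	108	IUGR
E281	3	female	137.1	IUGR
E303	4	male	132.1	IUGR
E320	5	male	125.5	IUGR
E329	5	male	116.9	IUGR
E311	6	female	90.4	IUGR
E312	6	male	78.4	IUGR
E384	7	female	118.1	IUGR
E338	8	female	130.4	IUGR
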