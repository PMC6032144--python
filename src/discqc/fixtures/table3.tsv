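donor_id	gender	age	sample_id	disc_level	mri_grade	compartment	ivd_total	ivd_any_zero	dd_total	dd_any_two
1	m	55	1	C4/5	4	AF	10	false	0	false
1	m	55	1	C4/5	4	NP	9	false	1	false
1	m	55	2	C5/6	4	AF	9	false	1	false
1	m	55	2	C5/6	4	NP	7	false	4	true
2	f	43	3	C4/5	3	AF	10	false	2	false
2	f	43	3	C4/5	3	NP	7	false	1	false
2	f	43	4	C5/6	3	AF	5	true	3	true
2	f	43	4	C5/6	3	NP	9	false	2	false
2	f	43	5	C6/7	3	AF	10	false	3	true
2	f	43	5	C6/7	3	NP	7	false	2	true
3	m	59	6	C4/5	3	AF	6	true	1	false
3	m	59	6	C4/5	3	NP	4	true	4	true
3	m	59	7	C5/6	3	AF	7	false	2	false
3	m	59	7	C5/6	3	NP	3	true	4	true
3	m	59	8	C6/7	3	AF	9	false	1	false
3	m	59	8	C6/7	3	NP	4	true	3	false
4	f	45	9	C5/6	3	AF	11	false	2	false
4	f	45	9	C5/6	3	NP	9	false	2	false
5	m	62	10	C3/4	4	AF	2	true	3	true
5	m	62	10	C3/4	4	NP	8	false	2	false
5	m	62	11	C4/5	4	AF	5	true	1	false
5	m	62	11	C4/5	4	NP	6	false	2	false
6	f	76	12	C4/5	3	AF	10	false	0	false
6	f	76	12	C4/5	3	NP	6	true	3	false
7	m	36	13	C4/5	4	AF	8	false	1	false
7	m	36	13	C4/5	4	NP	11	false	1	false
7	m	36	14	C5/6	4	AF	7	true	3	true
7	m	36	14	C5/6	4	NP	9	true	3	true
7	m	36	15	C6/7	4	AF	9	false	3	false
7	m	36	15	C6/7	4	NP	9	false	2	false
8	m	45	16	C3/4	4	AF	7	false	4	true
8	m	45	16	C3/4	4	NP	7	false	3	true
9	f	76	17	C4/5	4	AF	6	true	4	true
9	f	76	17	C4/5	4	NP	7	false	4	true
10	f	42	18	C5/6	4	AF	9	true	4	true
10	f	42	18	C5/6	4	NP	7	false	4	true
10	f	42	19	C6/7	3	AF	7	true	2	false
10	f	42	19	C6/7	3	NP	7	true	2	false
11	m	55	20	C4/5	4	AF	2	true	2	false
11	m	55	20	C4/5	4	NP	6	true	1	false
11	m	55	21	C5/6	4	AF	8	false	2	false
11	m	55	21	C5/6	4	NP	7	false	2	false
12	f	64	22	C3/4	4	AF	11	false	2	false
12	f	64	22	C3/4	4	NP	5	true	2	false
13	f	77	23	C6/7	4	AF	4	true	3	true
13	f	77	23	C6/7	4	NP	6	true	3	true
14	m	47	24	C5/6	4	AF	9	false	2	false
14	m	47	24	C5/6	4	NP	5	true	1	false
15	f	46	25	C4/5	4	AF	1	true	1	false
15	f	46	25	C4/5	4	NP	7	false	2	false
16	m	59	26	C5/6	4	AF	9	false	1	false
16	m	59	26	C5/6	4	NP	5	true	3	true
16	m	59	27	C6/7	3	AF	8	false	2	false
16	m	59	27	C6/7	3	NP	9	false	2	false
17	f	46	28	C5/6	3	AF	9	false	2	false
17	f	46	28	C5/6	3	NP	7	false	1	false
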