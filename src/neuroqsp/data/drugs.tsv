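drug	receptor	ki_nM	efficacy
aripiprazole	D2	0.66	0.25
aripiprazole	D1	410	0
aripiprazole	D4	44	0
aripiprazole	5HT1A	1.7	0.7
aripiprazole	5HT2A	3.4	0
aripiprazole	5HT3	628	0
aripiprazole	5HT6	574	0
aripiprazole	M1	6800	0
aripiprazole	alpha1	26	0
aripiprazole	alpha2	74	0
aripiprazole	H1	30	0
clozapine	D2	160	0
clozapine	D1	270	0
clozapine	D4	24	0
clozapine	5HT1A	140	0.3
clozapine	5HT2A	8	0
clozapine	5HT3	95	0
clozapine	5HT6	11	0
clozapine	M1	6	0
clozapine	alpha1	7	0
clozapine	alpha2	37	0
clozapine	H1	1.1	0
haloperidol	D2	1.2	0
haloperidol	D1	83	0
haloperidol	D4	2.3	0
haloperidol	5HT1A	1927	0
haloperidol	5HT2A	61	0
haloperidol	5HT3	3800	0
haloperidol	5HT6	6000	0
haloperidol	M1	10000	0
haloperidol	alpha1	12	0
haloperidol	alpha2	1130	0
haloperidol	H1	1800	0
olanzapine	D2	20	0
olanzapine	D1	52	0
olanzapine	D4	18	0
olanzapine	5HT1A	2063	0
olanzapine	5HT2A	3.3	0
olanzapine	5HT3	204	0
olanzapine	5HT6	10	0
olanzapine	M1	4.7	0
olanzapine	alpha1	54	0
olanzapine	alpha2	170	0
olanzapine	H1	2.2	0
paliperidone	D2	4.2	0
paliperidone	D1	250	0
paliperidone	D4	30	0
paliperidone	5HT1A	480	0
paliperidone	5HT2A	1.2	0
paliperidone	5HT3	1800	0
paliperidone	5HT6	2400	0
paliperidone	M1	10000	0
paliperidone	alpha1	4	0
paliperidone	alpha2	17	0
paliperidone	H1	19	0
quetiapine	D2	380	0
quetiapine	D1	990	0
quetiapine	D4	1600	0
quetiapine	5HT1A	320	0.3
quetiapine	5HT2A	220	0
quetiapine	5HT3	6000	0
quetiapine	5HT6	1860	0
quetiapine	M1	120	0
quetiapine	alpha1	22	0
quetiapine	alpha2	600	0
quetiapine	H1	7	0
risperidone	D2	3.2	0
risperidone	D1	240	0
risperidone	D4	7	0
risperidone	5HT1A	210	0
risperidone	5HT2A	0.2	0
risperidone	5HT3	9000	0
risperidone	5HT6	2000	0
risperidone	M1	10000	0
risperidone	alpha1	5	0
risperidone	alpha2	16	0
risperidone	H1	20	0
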