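table	organism	dataset	metric	n_opt	total	observed	expected	p
CSC	S. cerevisiae	Cramer (1)	cTE	24	25	23	9.8	1.5e-11
CSC	S. cerevisiae	Cramer (2)	cTE	24	26	18	10.2	1.2e-04
CSC	S. cerevisiae	Gresham	cTE	24	22	16	8.7	1.9e-04
CSC	S. cerevisiae	Cramer (1)	nTE	30	25	21	12.3	1.9e-05
CSC	S. cerevisiae	Cramer (2)	nTE	30	26	19	12.8	3.1e-03
CSC	S. cerevisiae	Gresham	nTE	30	22	17	10.8	2.4e-03
CSC	S. pombe	Mata (5)	cTE	28	27	24	12.4	9.2e-09
CSC	S. pombe	Gagneur	cTE	28	26	22	11.9	6.7e-07
CSC	S. pombe	Mata (5)	nTE	35	27	22	15.5	1.7e-03
CSC	S. pombe	Gagneur	nTE	35	26	21	14.9	3.5e-03
CPC	S. cerevisiae	Cramer (1)	cTE	24	23	23	9.0	3.5e-13
CPC	S. cerevisiae	Cramer (2)	cTE	24	22	17	8.7	1.9e-05
CPC	S. cerevisiae	Gresham	cTE	24	23	22	9.0	1.7e-11
CPC	S. cerevisiae	Cramer (1)	nTE	30	23	20	11.3	1.5e-05
CPC	S. cerevisiae	Cramer (2)	nTE	30	22	16	10.8	1.3e-02
CPC	S. cerevisiae	Gresham	nTE	30	23	19	11.3	1.5e-04
CPC	S. pombe	Bahler	cTE	28	27	25	12.4	3.8e-10
CPC	S. pombe	Mata (5)	cTE	28	21	18	9.6	2.1e-05
CPC	S. pombe	Gagneur	cTE	28	26	24	11.9	1.9e-09
CPC	S. pombe	Bahler	nTE	35	27	23	15.5	2.6e-04
CPC	S. pombe	Mata (5)	nTE	35	21	18	12.0	3.0e-03
CPC	S. pombe	Gagneur	nTE	35	26	22	14.9	5.7e-04
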