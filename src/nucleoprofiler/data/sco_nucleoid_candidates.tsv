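name	known_nap	category	locus_tag	accession	dnabinder_score	mw_kda	pi	empai_rep1	rank_rep1	empai_rep2	rank_rep2
AsnC-family regulator	0	D	SCO2140	Q9X7Z9		10.1	4.8	4.47	1	4.47	9
sIHF	1	D	SCO1480	Q9KXR9		11.5	10.4	3.49	2	6.4	7
YajQ	0	D	SCO4614	Q9F2U7		18	5.5	3.4	3	9.02	4
HupA	1	D	SCO2950	P0A3H5		9.9	9.5	3.24	4	9.1	3
Uncharacterised	0	U	SCO5783	O69959	0.59	17.1	7.1	2.95	5	1.36	25
RNA-binding	0	D	SCO5592	P0A4Q4		8.7	9.9	2.69	6	8.82	5
WXG-100	0	U	SCO5725	O86644	1.66	11.5	5.2	2.49	7	2.49	14
TerB	0	U	SCO3767	Q9F2L4	0.40	16.6	5.3	2.43	8	27.35	1
BldD	1	D	SCO1489	O52732		18.2	6.6	2.12	9	2.12	15
CRP	1	D	SCO3571	Q9XA42		24.6	6.2	1.99	10	2.81	11
YjqA	0	U	SCO3793	Q9F325	1.00	13.6	7.1	1.91	11	7.48	8
RNA polymerase	0	D	SCO4729	P60312		36.7	4.8	1.69	12	0.93	19
ARO/CYC	0	U	SCO2129	Q9X7Y8	1.44	15.9	6	1.53	13	1.53	21
AsnC-family regulator	0	D	SCO4493	Q9KYP0		17.9	5.6	1.28	14	0.93	20
SSBP	0	D	SCO3907	Q9X8U3		19.9	5.4	1.1	15	0.81	23
Lsr2	1	D	SCO3375	Q9X8N1		11.7	6.8	1.09	16	1.09	30
HtH regulator	0	D	SCO1839	Q9RJ29		7.6	10.5	1.07	17	11.84	2
Uncharacterised	0	U	SCO6482	Q9ZBJ2	0.03	16.1	5	0.73	18	1.5	22
Putative regulator	0	D	SCO1210	Q9FCA3		23.9	6.7	0.65	19	0.65	24
Putative regulator	0	D	SCO5405	Q9L2B5		18.3	6.7	0.62	20	1.62	18
AfsQ1	0	D	SCO4907	Q04942		25.1	5.8	0.61	21	0.81	22
Putative regulator	0	D	SCO4228	Q8CJU3		25.5	5.1	0.6	22	1.03	18
DeoR-family regulator	0	D	SCO3198	Q9KYU7		27	5.9	0.56	23	1.44	15
HupS	1	D	SCO5556	P0A3H7		22.3	11.2	0.49	24	0.71	24
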