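class	ER001	ER002	ER003	ER004	ER005	ER006	ER007	ER008	ER009	ER010	HER2001	HER2002	HER2003	HER2004	HER2005	HER2006	HER2007	HER2008	PROL001	PROL002	PROL003	PROL004	PROL005	PROL006	PROL007	PROL008	PROL009	PROL010	BAS001	BAS002	BAS003	BAS004	BAS005	BAS006	BAS007	BAS008
LumA	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3
LumB	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3
HER2E	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3
Basal	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0	2.0
Normal	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.2	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.4	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.6	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3	-0.3
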