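class	ER001	ER002	ER003	ER004	ER005	ER006	ER007	ER008	ER009	ER010	ER011	ER012	ER013	ER014	ER015	PROL001	PROL002	PROL003	PROL004	PROL005	PROL006	PROL007	PROL008	PROL009	PROL010	PROL011	PROL012	PROL013	PROL014	PROL015	BAS001	BAS002	BAS003	BAS004	BAS005
template	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-0.5	-0.5	-0.5	-0.5	-0.5
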