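id	chrom	pos	gene	age_label	ea	oa	eaf	beta_disc	se_disc	p_disc	beta_repl	se_repl	p_repl
rs2767486	1	65991203	LEPR	6m	G	A	0.16	0.158	0.021	8.8e-14	0.168	0.029	4.4e-09
rs13035244	2	25134009	ADCY3	1y	C	T	0.44	0.099	0.017	5.3e-09	0.095	0.023	3.5e-05
rs9922708	16	53831146	FTO	7y	T	C	0.44	0.147	0.021	2.4e-12	0.064	0.028	2.4e-02
rs6842303	4	17854055	LCORL	1.5y	T	G	0.28	0.105	0.019	2.8e-08	0.057	0.026	2.9e-02
rs10487505	7	127860163	LEP	1.5y	C	G	0.49	0.094	0.017	5.4e-08	0.051	0.023	2.6e-02
rs9469637	6	33895805	GRM4	birth	G	A	0.99	0.496	0.091	5.4e-08	0.140	0.127	2.7e-01
rs316344	6	2540316	SERPINB1	5y	A	C	0.34	0.137	0.023	1.4e-09	0.003	0.031	9.3e-01
rs72829508	10	98109442	OPALIN	3y	A	T	0.97	0.290	0.054	8.7e-08	0.063	0.078	4.2e-01
rs117320430	11	50242657	OR4C12	3m	T	C	0.02	0.305	0.054	2.1e-08	-0.009	0.070	9.0e-01
rs113084611	4	145622200	HHIP	6m	A	G	0.05	0.197	0.037	7.3e-08	-0.006	0.047	9.0e-01
rs112170166	2	730313	TMEM18	1.5y	C	A	0.98	0.370	0.069	8.1e-08	-0.034	0.088	7.0e-01
rs4880573	10	2707992	PFKP	8y	T	A	0.13	0.192	0.034	2.6e-08	-0.062	0.044	1.6e-01
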