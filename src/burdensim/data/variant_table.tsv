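dbsnp_id	variant	domain	af_percent	cadd_phred	functional	phenotype	misc_icl	misc_icl_hom	misc_hge	misc_hge_hom	covid19	covid19_hom
rs138728915	S6G	LP	0.094	8.2	Normal	MIS-C	1	0	1	0	0	0
rs764166999	D25N	IgV	0.001	0.05	Normal	MIS-C	0	0	1	0	0	0
rs201494649	R57K	IgV	0.031	8.68	Normal	MIS-C and COVID-19	0	0	1	0	2	0
rs751468271	F60S	IgV	0.019	11.13	Normal	MIS-C	0	0	1	0	0	0
rs145199317	S62G	IgV	0.573	0.08	Normal	MIS-C and COVID-19	1	0	11	0	1	0
rs573486977	G83D	IgV	0.004	13.52	Normal	MIS-C	0	0	2	0	0	0
rs144634509	A93T	IgV	0.053	5.48	Normal	MIS-C and COVID-19	1	0	2	0	1	0
-	L101Q	IgV	0	20.8	Reduced	MIS-C	1	0	0	0	0	0
rs749688648	T143M	IgC	0.003	0.001	Normal	COVID-19	0	0	0	0	1	0
rs146970792	R162Q	IgC	0.063	3.57	Normal	MIS-C	1	0	2	0	0	0
rs144634509	R162W	IgC	0.004	6.01	Normal	MIS-C	1	0	0	0	0	0
-	K168E	IgC	0	21.9	Normal	MIS-C	0	0	1	0	0	0
rs138408550	S176F	IgC	0.047	17.85	Normal	MIS-C	1	0	1	0	0	0
rs554947046	V191A	IgC	0.01	13.15	Normal	MIS-C	0	0	6	0	0	0
rs143894862	R209W	IgC	0.099	17.37	Normal	MIS-C and COVID-19	1	0	3	0	1	0
rs374252379	R215Q	IgC	0.003	0.04	Normal	MIS-C	0	0	1	0	0	0
rs146434143	R215X	IgC	0.006	34	Loss	MIS-C	0	0	1	0	0	0
rs368136851	S232L	-	0.006	10.05	Reduced	MIS-C	0	0	1	0	0	0
rs151174174	P299L	B30.2	1.360	17.52	Reduced	MIS-C and COVID-19	1	0	7	2	2	2
rs142207026	H311N	B30.2	0.002	-	Normal	MIS-C	1	0	0	0	0	0
rs372387302	S335C	B30.2	0.002	13.48	Normal	MIS-C	0	0	1	0	0	0
rs188974899	Y342C	B30.2	0.326	22.9	Reduced	MIS-C	0	0	3	0	0	0
rs141157357	R354H	B30.2	0.026	0.58	Reduced	MIS-C	0	0	1	0	0	0
rs148879045	Y446C	B30.2	0.045	11.02	Reduced	MIS-C	0	0	2	0	0	0
rs375876659	P456S	B30.2	0.009	1.8	Reduced	MIS-C	1	0	0	0	0	0
rs375021363	A475T	-	0.015	0.35	Normal	MIS-C	0	0	1	0	0	0
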