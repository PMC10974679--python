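# Default functional-group modification library (synthetic stand-in,
# curated in-house): 204 common organic R-groups, one attachment point
# each, marked with the dummy atom '*'.
fg_id	name	r_group_smiles
FG001	fluoro	*F
FG002	chloro	*Cl
FG003	bromo	*Br
FG004	iodo	*I
FG005	methyl	*C
FG006	ethyl	*CC
FG007	n-propyl	*CCC
FG008	isopropyl	*C(C)C
FG009	n-butyl	*CCCC
FG010	isobutyl	*CC(C)C
FG011	sec-butyl	*C(C)CC
FG012	tert-butyl	*C(C)(C)C
FG013	n-pentyl	*CCCCC
FG014	neopentyl	*CC(C)(C)C
FG015	n-hexyl	*CCCCCC
FG016	cyclopropyl	*C1CC1
FG017	cyclobutyl	*C1CCC1
FG018	cyclopentyl	*C1CCCC1
FG019	cyclohexyl	*C1CCCCC1
FG020	cyclopropylmethyl	*CC1CC1
FG021	cyclohexylmethyl	*CC1CCCCC1
FG022	vinyl	*C=C
FG023	allyl	*CC=C
FG024	isopropenyl	*C(=C)C
FG025	1-propenyl	*/C=C/C
FG026	ethynyl	*C#C
FG027	propargyl	*CC#C
FG028	1-propynyl	*C#CC
FG029	butadienyl	*C=CC=C
FG030	trifluoromethyl	*C(F)(F)F
FG031	difluoromethyl	*C(F)F
FG032	fluoromethyl	*CF
FG033	2,2,2-trifluoroethyl	*CC(F)(F)F
FG034	pentafluoroethyl	*C(F)(F)C(F)(F)F
FG035	trichloromethyl	*C(Cl)(Cl)Cl
FG036	chloromethyl	*CCl
FG037	2-chloroethyl	*CCCl
FG038	bromomethyl	*CBr
FG039	trifluoromethoxy	*OC(F)(F)F
FG040	difluoromethoxy	*OC(F)F
FG041	hydroxy	*O
FG042	methoxy	*OC
FG043	ethoxy	*OCC
FG044	n-propoxy	*OCCC
FG045	isopropoxy	*OC(C)C
FG046	n-butoxy	*OCCCC
FG047	tert-butoxy	*OC(C)(C)C
FG048	cyclopentyloxy	*OC1CCCC1
FG049	cyclohexyloxy	*OC1CCCCC1
FG050	phenoxy	*Oc1ccccc1
FG051	benzyloxy	*OCc1ccccc1
FG052	hydroxymethyl	*CO
FG053	2-hydroxyethyl	*CCO
FG054	methoxymethyl	*COC
FG055	2-methoxyethyl	*CCOC
FG056	methoxymethoxy	*OCOC
FG057	2-methoxyethoxy	*OCCOC
FG058	formyl	*C=O
FG059	acetyl	*C(C)=O
FG060	propanoyl	*C(=O)CC
FG061	butanoyl	*C(=O)CCC
FG062	isobutyryl	*C(=O)C(C)C
FG063	pivaloyl	*C(=O)C(C)(C)C
FG064	benzoyl	*C(=O)c1ccccc1
FG065	carboxy	*C(=O)O
FG066	methoxycarbonyl	*C(=O)OC
FG067	ethoxycarbonyl	*C(=O)OCC
FG068	tert-butoxycarbonyl	*C(=O)OC(C)(C)C
FG069	acetoxy	*OC(C)=O
FG070	benzoyloxy	*OC(=O)c1ccccc1
FG071	carboxymethyl	*CC(=O)O
FG072	2-oxopropyl	*CC(C)=O
FG073	glycidyl	*CC1CO1
FG074	oxetan-3-yl	*C1COC1
FG075	tetrahydrofuran-2-yl	*C1CCCO1
FG076	tetrahydropyran-4-yl	*C1CCOCC1
FG077	1,3-dioxolan-2-yl	*C1OCCO1
FG078	amino	*N
FG079	methylamino	*NC
FG080	dimethylamino	*N(C)C
FG081	ethylamino	*NCC
FG082	diethylamino	*N(CC)CC
FG083	isopropylamino	*NC(C)C
FG084	tert-butylamino	*NC(C)(C)C
FG085	cyclopropylamino	*NC1CC1
FG086	cyclohexylamino	*NC1CCCCC1
FG087	anilino	*Nc1ccccc1
FG088	benzylamino	*NCc1ccccc1
FG089	aminomethyl	*CN
FG090	2-aminoethyl	*CCN
FG091	methylaminomethyl	*CNC
FG092	dimethylaminomethyl	*CN(C)C
FG093	2-(dimethylamino)ethyl	*CCN(C)C
FG094	cyano	*C#N
FG095	cyanomethyl	*CC#N
FG096	2-cyanoethyl	*CCC#N
FG097	nitro	*[N+](=O)[O-]
FG098	nitromethyl	*C[N+](=O)[O-]
FG099	formamido	*NC=O
FG100	acetamido	*NC(C)=O
FG101	benzamido	*NC(=O)c1ccccc1
FG102	trifluoroacetamido	*NC(=O)C(F)(F)F
FG103	carbamoyl	*C(N)=O
FG104	methylcarbamoyl	*C(=O)NC
FG105	dimethylcarbamoyl	*C(=O)N(C)C
FG106	phenylcarbamoyl	*C(=O)Nc1ccccc1
FG107	ureido	*NC(N)=O
FG108	methylsulfonylamino	*NS(C)(=O)=O
FG109	pyrrolidin-1-yl	*N1CCCC1
FG110	piperidin-1-yl	*N1CCCCC1
FG111	azetidin-1-yl	*N1CCC1
FG112	morpholin-4-yl	*N1CCOCC1
FG113	piperazin-1-yl	*N1CCNCC1
FG114	4-methylpiperazin-1-yl	*N1CCN(C)CC1
FG115	pyrrolidin-1-ylmethyl	*CN1CCCC1
FG116	piperidin-1-ylmethyl	*CN1CCCCC1
FG117	morpholin-4-ylmethyl	*CN1CCOCC1
FG118	sulfanyl	*S
FG119	methylsulfanyl	*SC
FG120	ethylsulfanyl	*SCC
FG121	phenylsulfanyl	*Sc1ccccc1
FG122	methylsulfinyl	*S(C)=O
FG123	methylsulfonyl	*S(C)(=O)=O
FG124	ethylsulfonyl	*S(=O)(=O)CC
FG125	phenylsulfonyl	*S(=O)(=O)c1ccccc1
FG126	sulfamoyl	*S(N)(=O)=O
FG127	dimethylsulfamoyl	*S(=O)(=O)N(C)C
FG128	methylsulfanylmethyl	*CSC
FG129	phenyl	*c1ccccc1
FG130	benzyl	*Cc1ccccc1
FG131	2-phenylethyl	*CCc1ccccc1
FG132	3-phenylpropyl	*CCCc1ccccc1
FG133	1-phenylethyl	*C(C)c1ccccc1
FG134	benzhydryl	*C(c1ccccc1)c1ccccc1
FG135	naphthalen-1-yl	*c1cccc2ccccc12
FG136	naphthalen-2-yl	*c1ccc2ccccc2c1
FG137	pyridin-2-yl	*c1ccccn1
FG138	pyridin-3-yl	*c1cccnc1
FG139	pyridin-4-yl	*c1ccncc1
FG140	pyrimidin-2-yl	*c1ncccn1
FG141	pyrimidin-5-yl	*c1cncnc1
FG142	pyrazin-2-yl	*c1cnccn1
FG143	pyridazin-3-yl	*c1cccnn1
FG144	furan-2-yl	*c1ccco1
FG145	furan-3-yl	*c1ccoc1
FG146	thiophen-2-yl	*c1cccs1
FG147	thiophen-3-yl	*c1ccsc1
FG148	pyrrol-1-yl	*n1cccc1
FG149	pyrrol-2-yl	*c1ccc[nH]1
FG150	imidazol-1-yl	*n1ccnc1
FG151	imidazol-2-yl	*c1ncc[nH]1
FG152	pyrazol-1-yl	*n1cccn1
FG153	pyrazol-4-yl	*c1cn[nH]c1
FG154	oxazol-2-yl	*c1ncco1
FG155	isoxazol-3-yl	*c1ccon1
FG156	thiazol-2-yl	*c1nccs1
FG157	1,2,4-triazol-1-yl	*n1cncn1
FG158	tetrazol-5-yl	*c1nnn[nH]1
FG159	indol-3-yl	*c1c[nH]c2ccccc12
FG160	benzofuran-2-yl	*c1cc2ccccc2o1
FG161	benzothiophen-2-yl	*c1cc2ccccc2s1
FG162	quinolin-2-yl	*c1ccc2ccccc2n1
FG163	furan-2-ylmethyl	*Cc1ccco1
FG164	thiophen-2-ylmethyl	*Cc1cccs1
FG165	pyridin-2-ylmethyl	*Cc1ccccn1
FG166	pyridin-3-ylmethyl	*Cc1cccnc1
FG167	pyridin-4-ylmethyl	*Cc1ccncc1
FG168	imidazol-1-ylmethyl	*Cn1ccnc1
FG169	methylenedioxy-phenyl	*c1ccc2OCOc2c1
FG170	trimethylsilyl	*[Si](C)(C)C
FG171	phosphono	*P(=O)(O)O
FG172	dimethoxyphosphoryl	*P(=O)(OC)OC
FG173	azido	*N=[N+]=[N-]
FG174	2-fluorophenyl	*c1ccccc1F
FG175	3-fluorophenyl	*c1cccc(F)c1
FG176	4-fluorophenyl	*c1ccc(F)cc1
FG177	2-chlorophenyl	*c1ccccc1Cl
FG178	3-chlorophenyl	*c1cccc(Cl)c1
FG179	4-chlorophenyl	*c1ccc(Cl)cc1
FG180	2-bromophenyl	*c1ccccc1Br
FG181	3-bromophenyl	*c1cccc(Br)c1
FG182	4-bromophenyl	*c1ccc(Br)cc1
FG183	2-methylphenyl	*c1ccccc1C
FG184	3-methylphenyl	*c1cccc(C)c1
FG185	4-methylphenyl	*c1ccc(C)cc1
FG186	2-methoxyphenyl	*c1ccccc1OC
FG187	3-methoxyphenyl	*c1cccc(OC)c1
FG188	4-methoxyphenyl	*c1ccc(OC)cc1
FG189	2-trifluoromethylphenyl	*c1ccccc1C(F)(F)F
FG190	3-trifluoromethylphenyl	*c1cccc(C(F)(F)F)c1
FG191	4-trifluoromethylphenyl	*c1ccc(C(F)(F)F)cc1
FG192	2-hydroxyphenyl	*c1ccccc1O
FG193	3-hydroxyphenyl	*c1cccc(O)c1
FG194	4-hydroxyphenyl	*c1ccc(O)cc1
FG195	2-cyanophenyl	*c1ccccc1C#N
FG196	3-cyanophenyl	*c1cccc(C#N)c1
FG197	4-cyanophenyl	*c1ccc(C#N)cc1
FG198	2-nitrophenyl	*c1ccccc1[N+](=O)[O-]
FG199	3-nitrophenyl	*c1cccc([N+](=O)[O-])c1
FG200	4-nitrophenyl	*c1ccc([N+](=O)[O-])cc1
FG201	2-aminophenyl	*c1ccccc1N
FG202	3-aminophenyl	*c1cccc(N)c1
FG203	4-aminophenyl	*c1ccc(N)cc1
FG204	3,4-dichlorophenyl	*c1ccc(Cl)c(Cl)c1
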