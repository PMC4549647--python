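id	chrom	pos	ref	alt	flags
ss001	chrS	20000	G	A	
ss002	chrS	60003	G	C	
ss003	chrS	100001	G	T	
ss004	chrS	140001	G	C	
ss005	chrS	181000	A	G	
ss006	chrS	182000	A	G	
ss007	chrS	183000	A	G	
ss008	chrS	184000	A	G	
ss009	chrS	185000	A	G	
ss010	chrS	186000	A	G	
ss011	chrS	187000	A	G	
ss012	chrS	188000	A	G	
ss013	chrS	189000	A	G	
ss014	chrS	190000	A	G	
ss015	chrS	191000	A	G	
ss016	chrS	192000	A	G	
ss017	chrS	193000	A	G	
ss018	chrS	194000	A	G	
ss019	chrS	195000	A	G	
ss020	chrS	196000	A	G	NMD_target
ss021	chrS	197000	A	G	NMD_target
ss022	chrS	198000	A	G	NMD_target
ss023	chrS	199000	A	G	NMD_target
ss024	chrS	200000	A	G	
ss025	chrS	201000	A	G	
ss026	chrS	202000	A	G	
ss027	chrS	203000	A	G	
ss028	chrS	204000	A	G	
ss029	chrS	205000	A	G	
ss030	chrS	206000	A	G	
ss031	chrS	207000	A	G	
ss032	chrS	208000	A	G	
ss033	chrS	209000	A	G	
ss034	chrS	210000	A	G	
ss035	chrS	211000	A	G	
ss036	chrS	212000	A	G	
ss037	chrS	213000	A	G	
ss038	chrS	214000	A	G	
ss039	chrS	215000	A	G	
ss040	chrS	216000	A	G	
ss041	chrS	217000	A	G	
ss042	chrS	218000	A	G	
ss043	chrS	219000	A	G	
ss044	chrS	220000	A	G	
ss045	chrS	260010	A	G	
ss046	chrS	260050	A	G	
ss047	chrS	260750	A	G	
ss048	chrS	19000	A	G	
ss049	chrS	18000	A	G	
ss050	chrS	59000	A	G	
ss051	chrS	58000	A	G	
ss052	chrS	99000	A	G	
ss053	chrS	98000	A	G	
ss054	chrS	139000	A	G	
ss055	chrS	138000	A	G	
ss056	chrS	179000	A	G	
ss057	chrS	178000	A	G	
ss058	chrS	259000	A	G	
ss059	chrS	258000	A	G	
ss060	chrS	21400	A	G	
ss061	chrS	22400	A	G	
ss062	chrS	61400	A	G	
ss063	chrS	62400	A	G	
ss064	chrS	101400	A	G	
ss065	chrS	102400	A	G	
ss066	chrS	141400	A	G	
ss067	chrS	5000	A	G	
ss068	chrS	6000	A	G	
ss069	chrS	7000	A	G	
ss070	chrS	300000	A	G	
ss071	chrS	310000	A	G	
ss072	chrS	320000	A	G	
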