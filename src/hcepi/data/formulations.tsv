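atc5	route	abbreviation	formulation_name	components	duration_class	hc_type	hc_class	days_per_unit	n_individuals	n_purchases
G03AA10	oral	GSD/EE	gestodene and ethinylestradiol	progestin_estrogen	short_acting	COC_3rd_gen	CHC	28	27651	370347
G03AA12	oral	DRSP/EE	drospirenone and ethinylestradiol	progestin_estrogen	short_acting	COC_4th_gen	CHC	28	26030	425757
G02BA03	intrauterine	LNG IUD	plastic IUD with progestogen	progestin_only	long_acting	IUD_progestogen	POC		24465	37431
G03AC09	oral	DSG	desogestrel	progestin_only	short_acting	POP	POC	28	16557	79335
G02BB01	intravaginal	CHC RING	vaginal ring with progestogen and estrogen	progestin_estrogen	short_acting	CHC_ring	CHC	28	13376	160743
G03AA13	transdermal	NGMN/EE	norelgestromin and ethinylestradiol	progestin_estrogen	short_acting	CHC_patch	CHC	28	13182	125341
G03AA16	oral	DNG/EE	dienogest and ethinylestradiol	progestin_estrogen	short_acting	COC_4th_gen	CHC	28	12765	178867
G03AA09	oral	DSG/EE	desogestrel and ethinylestradiol	progestin_estrogen	short_acting	COC_3rd_gen	CHC	28	11229	118347
G03HB01	oral	CPA/EE	cyproterone and ethinylestradiol	progestin_estrogen	short_acting	COC_anti_androgenic	CHC	28	5068	52309
G03AC03	oral	LNG	levonorgestrel	progestin_only	short_acting	POP	POC	35	4318	13758
G03AA15	oral	CMA/EE	chlormadinone and ethinylestradiol	progestin_estrogen	short_acting	COC_anti_androgenic	CHC	28	3063	21879
G03AA07	oral	LNG/EE	levonorgestrel and ethinylestradiol	progestin_estrogen	short_acting	COC_2nd_gen	CHC	28	2763	17433
G03AB03	oral	LNG/EE(s)	levonorgestrel and ethinylestradiol	progestin_estrogen	short_acting	COC_2nd_gen	CHC	28	2350	33275
G03AC08	subdermal	ENG	etonogestrel	progestin_only	long_acting	implant	POC		1576	1979
G03AA11	oral	NGM/EE	norgestimate and ethinylestradiol	progestin_estrogen	short_acting	COC_3rd_gen	CHC	28	972	12215
G03AB08	oral	DNG/E2V	dienogest and estradiol valerate	progestin_estrogen	short_acting	COC_estradiol	CHC	28	574	5336
G03AC10	oral	DRSP	drospirenone	progestin_only	short_acting	POP	POC	28	400	1232
G03AB06	oral	GSD/EE(s)	gestodene and ethinylestradiol	progestin_estrogen	short_acting	COC_3rd_gen	CHC	28	397	1944
G03AA14	oral	NOMAC/E2	nomegestrol and estradiol	progestin_estrogen	short_acting	COC_estradiol	CHC	28	328	2017
G03AB05	oral	DSG/EE(s)	desogestrel and ethinylestradiol	progestin_estrogen	short_acting	COC_3rd_gen	CHC	28	309	2562
G03AA10	transdermal	GSD/EE(p)	gestodene and ethinylestradiol	progestin_estrogen	short_acting	CHC_patch	CHC	28	261	514
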