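# Published large-cohort estimates for 17 obesity-related traits (Japanese adults): genetic correlations (rg +/- SE, bivariate GREML,
# significance: ** p<0.01, * p<0.05, + p<0.1) and phenotypic correlations (rp, Pearson on sex- and age-adjusted z-scores).
trait1	trait2	rg	rg_se	rg_sig	rp
SBP	DBP	0.688	0.100	**	0.737
SBP	TG	-0.179	0.175		0.103
SBP	HDL-C	0.207	0.135	+	-0.011
SBP	ht	-0.174	0.106	*	-0.018
SBP	wt	-0.107	0.156		0.189
SBP	BMI	0.023	0.151		0.208
SBP	WC	-0.044	0.167		0.186
SBP	WHtR	0.057	0.152		0.188
SBP	uCre	-0.095	0.307		-0.062
SBP	uCl	-0.075	0.260		0.019
SBP	uK	-0.555	0.389	+	-0.090
SBP	CysC	-0.096	0.130		0.016
SBP	SCre	-0.082	0.132		-0.021
SBP	SUA	0.051	0.119		0.080
SBP	BUN	-0.276	0.176	+	-0.064
SBP	Hb	-0.025	0.146		0.135
DBP	TG	0.070	0.136		0.108
DBP	HDL-C	0.117	0.110		-0.016
DBP	ht	-0.026	0.086		0.027
DBP	wt	-0.026	0.126		0.211
DBP	BMI	-0.020	0.128		0.210
DBP	WC	-0.030	0.139		0.193
DBP	WHtR	-0.014	0.130		0.179
DBP	uCre	-0.069	0.253		-0.044
DBP	uCl	-0.161	0.220		0.006
DBP	uK	-0.269	0.300		-0.071
DBP	CysC	0.003	0.107		0.019
DBP	SCre	0.100	0.110		0.002
DBP	SUA	0.059	0.100		0.108
DBP	BUN	-0.169	0.143		-0.076
DBP	Hb	0.082	0.118		0.219
TG	HDL-C	-0.429	0.072	**	-0.397
TG	ht	-0.042	0.070		0.004
TG	wt	0.068	0.100		0.232
TG	BMI	0.109	0.100		0.245
TG	WC	0.143	0.107		0.258
TG	WHtR	0.161	0.100	+	0.252
TG	uCre	-0.262	0.219		-0.020
TG	uCl	-0.023	0.177		0.035
TG	uK	-0.117	0.240		-0.015
TG	CysC	0.052	0.087		0.084
TG	SCre	0.073	0.089		0.061
TG	SUA	0.212	0.079	**	0.167
TG	BUN	0.116	0.119		-0.033
TG	Hb	0.122	0.099		0.142
HDL-C	ht	0.007	0.056		-0.027
HDL-C	wt	-0.191	0.075	**	-0.312
HDL-C	BMI	-0.202	0.076	**	-0.320
HDL-C	WC	-0.221	0.081	**	-0.329
HDL-C	WHtR	-0.198	0.077	**	-0.315
HDL-C	uCre	-0.180	0.166		-0.087
HDL-C	uCl	-0.270	0.145	*	-0.021
HDL-C	uK	-0.203	0.195	*	-0.005
HDL-C	CysC	-0.215	0.067	**	-0.221
HDL-C	SCre	-0.087	0.070		-0.070
HDL-C	SUA	-0.109	0.064	*	-0.142
HDL-C	BUN	0.015	0.093		0.070
HDL-C	Hb	-0.021	0.079		-0.069
ht	wt	0.454	0.053	**	0.363
ht	BMI	-0.197	0.063	**	-0.085
ht	WC	0.105	0.068	+	0.123
ht	WHtR	-0.377	0.062	**	-0.197
ht	uCre	0.104	0.131		0.046
ht	uCl	0.125	0.112		0.016
ht	uK	0.286	0.172		0.042
ht	CysC	-0.056	0.055		0.020
ht	SCre	0.035	0.056		0.093
ht	SUA	0.013	0.051		0.025
ht	BUN	0.071	0.073		-0.014
ht	Hb	-0.002	0.063		0.035
wt	BMI	0.784	0.029	**	0.893
wt	WC	0.825	0.028	**	0.870
wt	WHtR	0.553	0.058	**	0.739
wt	uCre	0.297	0.193	+	0.066
wt	uCl	0.477	0.169	**	0.098
wt	uK	0.559	0.266	**	0.050
wt	CysC	0.034	0.078		0.166
wt	SCre	-0.003	0.080		0.096
wt	SUA	0.084	0.071		0.228
wt	BUN	-0.070	0.105		0.017
wt	Hb	-0.026	0.090		0.143
BMI	WC	0.829	0.028	**	0.874
BMI	WHtR	0.874	0.021	**	0.890
BMI	uCre	0.243	0.193	+	0.049
BMI	uCl	0.436	0.169	**	0.096
BMI	uK	0.380	0.239	*	0.033
BMI	CysC	0.078	0.079		0.168
BMI	SCre	-0.021	0.081		0.063
BMI	SUA	0.070	0.072		0.230
BMI	BUN	-0.134	0.107		0.026
BMI	Hb	-0.021	0.091		0.139
WC	WHtR	0.881	0.018	**	0.947
WC	uCre	0.228	0.208		0.049
WC	uCl	0.482	0.184	**	0.086
WC	uK	0.474	0.269	*	0.033
WC	CysC	0.119	0.085	+	0.174
WC	SCre	-0.078	0.089		0.042
WC	SUA	0.105	0.077	+	0.240
WC	BUN	-0.093	0.116		0.004
WC	Hb	0.049	0.097		0.161
WHtR	uCre	0.164	0.193		0.034
WHtR	uCl	0.391	0.170	**	0.079
WHtR	uK	0.290	0.233	+	0.019
WHtR	CysC	0.140	0.079	*	0.167
WHtR	SCre	-0.083	0.083		0.013
WHtR	SUA	0.085	0.073		0.227
WHtR	BUN	-0.118	0.109		0.009
WHtR	Hb	0.051	0.091		0.147
uCre	uCl	0.520	0.260	+	0.388
uCre	uK	0.374	0.345		0.581
uCre	CysC	0.139	0.160		0.109
uCre	SCre	-0.015	0.167		0.137
uCre	SUA	-0.091	0.152		0.058
uCre	BUN	-0.152	0.229		0.149
uCre	Hb	-0.137	0.192		0.033
uCl	uK	0.575	0.245	+	0.589
uCl	CysC	-0.281	0.143	*	-0.067
uCl	SCre	-0.481	0.156	**	-0.073
uCl	SUA	-0.175	0.128	+	-0.083
uCl	BUN	-0.137	0.193		0.151
uCl	Hb	0.062	0.158		-0.034
uK	CysC	-0.185	0.196		-0.005
uK	SCre	-0.510	0.260	**	0.039
uK	SUA	-0.203	0.186		0.027
uK	BUN	-0.501	0.342	*	0.217
uK	Hb	0.044	0.210		-0.001
CysC	SCre	0.614	0.045	**	0.543
CysC	SUA	0.340	0.057	**	0.335
CysC	BUN	0.093	0.090		0.190
CysC	Hb	0.143	0.079	*	0.051
SCre	SUA	0.285	0.059	**	0.333
SCre	BUN	0.246	0.086	**	0.311
SCre	Hb	0.046	0.080		-0.015
SUA	BUN	-0.061	0.088		0.156
SUA	Hb	-0.015	0.074		0.146
BUN	Hb	-0.091	0.104		-0.092
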