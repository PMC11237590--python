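bioproject	source	substrate	region	n_samples	first_day	last_day	n_time_points
PRJEB15657	MGnify	carrot	V4	310	1	60	12
PRJNA595462	SRA	cucumber	V4	60	0	64	5
PRJNA544161	SRA	red pepper and meju (doubanjiang)	V3-V4	28	30	720	3
PRJNA751723	SRA	kimchi cabbage mix	V3-V4	192	0	30	6
PRJNA564474	SRA	kimchi cabbage mix	V3-V4	52	1	50	8
PRJNA689239	SRA	cabbage (paocai)	V3-V4	18	1	30	6
PRJNA473189	SRA	red pepper	V4	80	3	109	10
PRJNA485506	FoodMicrobioNet	cucumber	V3-V4	72	1	14	7
PRJNA662831	SRA	Chinese sauerkraut	V4	45	3	15	2
PRJNA418790	SRA	kimchi (vegan/traditional)	V4	74	0	3	4
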