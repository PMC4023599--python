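gene_id	gene_accession	group	chromosome	start	end	strand	protein_length	intron_count	pattern	pattern_text	ortholog_ids
VvbZIP01	VIT_01s0011g03230	J	1	2941266	2946275	+	453	10	b	b	46*,20,45,26,65,21,57,47,22,50
VvbZIP02	VIT_01s0010g00930	C	1	16444033	16444682	-	195	0	h	i	42,58*,48,43,3,8*,70,2,44,53,7,11,41,5,68,6,16,4
VvbZIP03	VIT_02s0025g01020	D	2	989255	996186	+	398	10	a	a	55(GBF3)*,54(GBF2)*,16,68,41
VvbZIP04	VIT_02s0012g02250	D	2	9137736	9153313	-	413	11	a	a	55,54,16*,68*,41,44,42,43,58,3,70,8,48
VvbZIP05	VIT_03s0038g00860	F	3	689247	693308	+	676	5	c	c	29*,30*,18,52,69,51,59,31,33,61,34,74
VvbZIP06	VIT_03s0038g02420	I	3	1679507	1683223	+	271	1	h	i	23*,19*,24
VvbZIP07	VIT_03s0038g04450	C	3	3227416	3228660	-	157	0	h	i	44,11,2,53,48,3,42,43,58,8,1,6,7,5,68,70
VvbZIP08	VIT_03s0063g00310	A	3	3887073	3890514	-	409	4	a	a	37(ABF3)*,36,38(ABF4/AREB2)*,35(ABF1)*,15,66,12,67,39,14,13,40
VvbZIP09	VIT_04s0008g02750	B	4	2284121	2287115	-	349	5	d	d	9*,63,10,2,53,42,25,44,58,3,48,68,11
VvbZIP10	VIT_04s0008g05210	G	4	4716191	4719252	+	169	3	f	f	56(HY5)*,64
VvbZIP11	VIT_04s0069g01150	A	4	9841491	9842587	+	57	1	a	a	66,12,37,36,35,38,39
VvbZIP12	VIT_04s0023g01360	D	4	17832626	17863952	+	364	10	a	a	41*,16,68,55,54,42,70,3,58,43,48,8,44,18
VvbZIP13	VIT_04s0023g02430	C	4	18983616	18984767	+	249	0	h	i	44,11,2,53,48,42,58,3,43,8,7,6,1,5
VvbZIP14	VIT_05s0077g01140	C	5	878161	879142	-	154	0	h	i	53,2,44,11,58,3,5,48,7,1
VvbZIP15	VIT_05s0020g01090	G	5	2860048	2863747	+	210	3	h	i	64(HYH)*,56
VvbZIP16	VIT_05s0102g01120	F	5	23226450	23231749	-	425	3	c	c	69,59,18,52,51,29,30,61,33,31,34,74
VvbZIP17	VIT_06s0004g08070	F	6	8835674	8841051	-	342	3	c	c	18*,52*,59,69,51,29,30,33,61,31,74,34
VvbZIP18	VIT_06s0009g01790	A	6	13809459	13815625	-	248	2	a	a	66,12,35,38,36,67,39,40,14,13,37,15
VvbZIP19	VIT_06s0080g00340	A	6	20262007	20263157	+	324	2	a	a	67(DPBF2)*,39,66,12,35,36,38,15,37,40
VvbZIP20	VIT_06s0080g00360	J	6	20304714	20311349	-	500	10	g	g	21*,65,45,20,26,46,22,50,47,57
VvbZIP21	VIT_07s0141g00170	B	7	116657	126811	-	452	5	d	d	25,10,63,9
VvbZIP22	VIT_07s0005g01450	C	7	3987031	3988120	+	145	0	h	i	53*,44,2,11,42,3,6,48,7,58,43,8,16,1,68
VvbZIP23	VIT_07s0031g01320	J	7	17404970	17410595	+	349	7	b	b	47,57*,50,22,20,45,26,21,46,65
VvbZIP24	VIT_08s0040g00870	H	8	11857207	11860728	-	819	1	h	i	17,28,49*
VvbZIP25	VIT_08s0007g03420	A	8	17372100	17378057	-	400	0	a	a	39(ABI5)*,35,67,66,38,37,36,12,13,15,40,14
VvbZIP26	VIT_08s0007g03640	UC	8	17579864	17586189	+	496	5	a	a	62
VvbZIP27	VIT_08s0007g05170	J	8	19088004	19098613	-	451	10	b	b	45,20,26,46,21,65,57,50,22,47
VvbZIP28	VIT_08s0007g06160	J	8	19963578	19968190	-	491	10	b	b	65*,21,45,20,26,46,22,57,50,47
VvbZIP29	VIT_12s0028g02590	E	12	3366293	3367561	-	295	3	e	e	61,34,51,69,18,52,59,30,29,72,33,31
VvbZIP30	VIT_12s0055g00420	A	12	13276799	13300251	+	299	3	a	a	13,40,12,66,67,35,37,38,36,39,14
VvbZIP31	VIT_12s0034g00110	A	12	15485471	15491224	+	99	3	a	a	66,12,37,36,35,38,39
VvbZIP32	VIT_12s0035g00620	E	12	20038502	20045379	+	374	3	e	e	61,34,69,59,18,51,29,52,30
VvbZIP33	VIT_13s0067g02900	F	13	1562503	1569804	+	359	3	c	c	18*,52,59,69,51,29,30,33,61,31,34,74,72
VvbZIP34	VIT_13s0175g00120	A	13	15049338	15072969	+	325	2	a	a	66,12,35,67,38,37,36,39,15,14
VvbZIP35	VIT_13s0084g00660	J	13	19780668	19805654	-	469	10	b	b	45,26,20,46,21,65,57,22,50,47
VvbZIP36	VIT_13s0158g00380	I	13	21283084	21284766	-	286	1	h	i	23,19,24
VvbZIP37	VIT_14s0060g01210	C	14	959578	961198	-	145	0	h	i	53,11,2,44,1,48,58,3,8,7,42,43,70
VvbZIP38	VIT_14s0030g02200	B	14	7402807	7408597	+	423	5	d	d	63,10,25,9
VvbZIP39	VIT_14s0083g00700	C	14	22839619	22840360	-	198	0	h	i	42*,43*,58,3*,48,8,70,44,2,53,6,11,41,7,5,68
VvbZIP40	VIT_15s0046g01440	D	15	18416554	18423462	-	430	11	a	a	55(GBF3)*,54(GBF2)*,16,68,41,3,42,43,70,58
VvbZIP41	VIT_18s0122g00500	UC	18	420616	423564	+	322	2	f	f	60*
VvbZIP42	VIT_18s0001g04470	J	18	3861987	3867762	-	363	7	b	b	57,47,50,22*,26,20,65,45,21,46
VvbZIP43	VIT_18s0001g04500	A	18	3875315	3878509	+	311	2	a	a	12,66,35,36,39,38,37,14,15,67,40,13
VvbZIP44	VIT_18s0001g08710	C	18	7185268	7185664	-	81	0	h	i	7,6,4,5,2,3
VvbZIP45	VIT_18s0001g10450	A	18	8761978	8769742	-	447	3	a	a	36(ABF2/AREB1)*,35,37(ABF3)*,38,66,12,39,15*,67
VvbZIP46	VIT_18s0001g12120	D	18	10309606	10313842	+	396	10	a	a	41,16,68,55,54,43,58,42,3,48,70,8
VvbZIP47	VIT_18s0001g13040	C	18	11138196	11139020	+	154	0	h	i	44,11,2,53,48,3,42,58,43,1,7,6,8,5
VvbZIP48	VIT_18s0001g13740	F	18	11745490	11746413	-	187	3	c	c	30,29,51,69,52,18,59,33,31,61,34
VvbZIP49	VIT_18s0001g14890	A	18	12936974	12937903	-	214	2	a	a	14(FD)*,66,12,37,36,39,38,35,27*
VvbZIP50	VIT_18s0076g00330	F	18	16209694	16218061	+	350	3	c	c	51,18,69,59,52,29,30,31,61,33,74,34
VvbZIP51	VIT_18s0072g00470	A	18	19680318	19687522	+	275	3	a	a	13,40,66,12,39,36
VvbZIP52	VIT_19s0014g01780	E	19	1945207	1947498	-	309	3	e	e	61,34,51,18,52,69,59,30,29,72,33,31
VvbZIP53	VIT_19s0015g01020	A	19	9101591	9112651	-	251	2	g	g	36,12
VvbZIP54	VIT_18s0001g03010	E	18_random	3068050	3070292	-	272	3	e	e	61,34,69,51,59
VvbZIP55	VIT_00s0541g00020	C	Un	31593865	31594595	-	194	0	h	i	6,5,7,44,42,58,2,3,11,48,53,43,70,8,1,4
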