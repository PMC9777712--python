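Gene	Strand	Start	End	Size	Anticodon	StartCodon	StopCodon	IntergenicNucleotides
trnI	J	1	65	65	GAT
trnQ	N	66	140	75	TTG			0
trnM	J	136	206	71	CAT			-5
nad2	J	206	1234	1029		ATA	TAA	-1
trnW	J	1232	1306	75	TCA			-3
trnC	N	1333	1396	64	GCA			2
trnY	N	1398	1465	68	GTA			1
cox1	J	1458	2997	1540		ATT	T	-8
trnL2	J	2998	3062	65	TAA			0
cox2	J	3065	3749	685		ATG	T	2
trnK	J	3750	3820	71	CTT			0
trnD	J	3821	3886	66	GTC			0
atp8	J	3887	4048	162		ATC	TAA	0
atp6	J	4042	4719	678		ATG	TAA	-7
cox3	J	4719	5507	789		ATG	TAA	-1
trnG	J	5509	5576	68	TCC			1
nad3	J	5576	5929	354		ATT	TAG	-1
trnA	J	5930	5990	61	TGC			0
trnR	J	5993	6058	66	TCG			2
trnN	J	6059	6124	66	GTT			0
trnS1	J	6125	6191	67	GCT			0
trnE	J	6193	6261	69	TTC			1
trnF	N	6257	6325	69	GAA			-5
nad5	N	6324	8052	1729		ATT	T	-2
trnH	N	8053	8117	65	GTG			0
nad4	N	8118	9456	1339		ATG	T	0
nad4l	N	9450	9743	294		ATT	TAA	-7
trnT	J	9744	9812	69	TGT			0
trnP	N	9811	9875	65	TGG			-2
nad6	J	9877	10401	525		ATT	TAA	1
cob	J	10401	11537	1137		ATG	TAG	-1
trnS2	J	11536	11603	68	TGA			-2
nad1	N	11620	12570	951		TTG	TAG	16
trnL1	N	12571	12636	66	TAG			0
rrnL	N	12637	13948	1312				0
trnV	N	13954	14024	71	TAC			5
rrnS	N	14025	14810	786				0
CR	J	14811	16137	1327
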