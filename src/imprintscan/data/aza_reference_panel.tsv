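locus_id	status	sample	untreated	treated
chr1:203742262-203768466	affected	GM19099	2.54	1.42
chr1:203742262-203768466	affected	GM19141	2.74	1.24
chr1:205886352-205961039	affected	GM19099	2.21	1.38
chr1:205886352-205961039	affected	GM19141	2.20	1.49
chr1:231822688-231871795	affected	GM19099	1.78	1.11
chr1:231822688-231871795	affected	GM19141	4.69	2.59
chr4:79778447-79803457	affected	GM19099	2.47	1.78
chr4:79778447-79803457	affected	GM19141	2.1	1.27
chr5:173100613-173139917	affected	GM19099	2.33	1.27
chr5:173100613-173139917	affected	GM19141	2.08	1.15
chr5:9599989-9600708	affected	GM19099	3.02	1.58
chr5:9599989-9600708	affected	GM19141	1.47	1.06
chr6:139658229-139733915	affected	GM19099	3.16	2.36
chr6:139658229-139733915	affected	GM19141	3.53	2.53
chr6:80016628-80042343	affected	GM19099	3.16	2.36
chr6:80016628-80042343	affected	GM19141	2.71	1.25
chr7:71159735-71207121	affected	GM19099	1.51	1.05
chr7:71159735-71207121	affected	GM19141	5.76	1.76
chr11:3036678-3063235	affected	GM19099	4.64	2.94
chr11:3036678-3063235	affected	GM19141	4.63	3.18
chr11:7376868-7440901	affected	GM19099	2.09	1.31
chr11:7376868-7440901	affected	GM19141	3.48	2.15
chr11:123521934-123522703	affected	GM19099	2.02	1.37
chr11:123521934-123522703	affected	GM19141	2.12	1.37
chr12:120055848-120087505	affected	GM19099	2.23	1.08
chr12:120055848-120087505	affected	GM19141	1.81	1.24
chr13:109958305-109963202	affected	GM19099	3.25	1.5
chr13:109958305-109963202	affected	GM19141	2.58	1.84
chr14:60959560-61030659	affected	GM19099	2.17	1.64
chr14:60959560-61030659	affected	GM19141	1.92	1.43
chr15:76345564-76360674	affected	GM19099	2.15	1.58
chr15:76345564-76360674	affected	GM19141	8.56	5.77
chr15:94684325-94711444	affected	GM19099	3.11	2.13
chr15:94684325-94711444	affected	GM19141	5.45	3.28
chr17:10022884-10022981	affected	GM19099	4.24	2.21
chr17:10022884-10022981	affected	GM19141	2.13	1.44
chr17:14190861-14192673	affected	GM19099	2.37	1.68
chr17:14190861-14192673	affected	GM19141	2.34	1.60
chr20:3179134-3334482	affected	GM19099	3.47	2.08
chr20:3179134-3334482	affected	GM19141	1.92	1.45
chr20:46050433-46119516	affected	GM19099	2.22	1.54
chr20:46050433-46119516	affected	GM19141	2.48	1.65
chr20:46358273-46404570	affected	GM19099	2.06	1.27
chr20:46358273-46404570	affected	GM19141	3.15	1.59
chr20:56848505-56882141	affected	GM19099	6.46	4.14
chr20:56848505-56882141	affected	GM19141	3.62	2.06
chr21:42665938-42688945	affected	GM19099	1.47	1.04
chr21:42665938-42688945	affected	GM19141	4.19	1.43
chr22:28762403-28805154	affected	GM19099	1.43	1.03
chr22:28762403-28805154	affected	GM19141	4.25	2.23
chr22:29598129-29633708	affected	GM19099	2.41	1.84
chr22:29598129-29633708	affected	GM19141	2.86	1.71
chr1:218867493-218900613	unaffected	GM19141	6.38	6.26
chr1:229837731-230086433	unaffected	GM19141	4.64	4.85
chr2:219372907-219379842	unaffected	GM19099	3.84	2.54
chr2:219372907-219379842	unaffected	GM19141	1.25	1.62
chr2:88252911-88265923	unaffected	GM19099	2.43	3.37
chr3:62165281-62250653	unaffected	GM19099	4.02	3.09
chr3:62165281-62250653	unaffected	GM19141	3.65	5.10
chr3:120375223-120399317	unaffected	GM19099	4.12	3.68
chr3:120375223-120399317	unaffected	GM19141	1.23	1.33
chr4:1654935-1655009	unaffected	GM19099	1.93	2.04
chr4:1654935-1655009	unaffected	GM19141	2.30	2.13
chr4:5767823-5801057	unaffected	GM19099	1.68	1.78
chr4:5767823-5801057	unaffected	GM19141	3.47	3.11
chr4:6698225-6722860	unaffected	GM19141	3.9	3.99
chr4:107011829-107032181	unaffected	GM19141	4.34	4.27
chr4:142529192-142768065	unaffected	GM19099	5.11	5.47
chr5:14801236-14922709	unaffected	GM19099	1.42	1.35
chr5:14801236-14922709	unaffected	GM19141	7.59	8.63
chr5:82347320-82386566	unaffected	GM19141	2.1	2.23
chr6:654765-656792	unaffected	GM19099	3.18	3.13
chr6:132659162-132759924	unaffected	GM19099	2.02	2.08
chr6:132659162-132759924	unaffected	GM19141	3.07	3.03
chr8:511306-580861	unaffected	GM19099	3.54	2.76
chr8:511306-580861	unaffected	GM19141	2.33	2.79
chr9:5296824-5301171	unaffected	GM19141	3.83	3.91
chr9:117025707-117204395	unaffected	GM19099	2.22	2.18
chr10:363048-477973	unaffected	GM19099	3.56	2.48
chr10:363048-477973	unaffected	GM19141	1.25	1.73
chr10:13817200-14106528	unaffected	GM19141	3.93	4.13
chr11:6879025-6898447	unaffected	GM19099	2.81	2.20
chr11:6879025-6898447	unaffected	GM19141	1.63	2.15
chr11:70187425-70240934	unaffected	GM19099	2.73	2.13
chr11:70187425-70240934	unaffected	GM19141	1.52	1.83
chr13:18766583-18804422	unaffected	GM19099	3.50	3.03
chr13:18766583-18804422	unaffected	GM19141	3.52	4.30
chr12:88415605-88431297	unaffected	GM19099	2.18	2.27
chr12:88415605-88431297	unaffected	GM19141	2.66	2.62
chr14:24047434-24096337	unaffected	GM19099	2.44	2.01
chr14:24047434-24096337	unaffected	GM19141	4.27	5.26
chr14:36198687-36216226	unaffected	GM19099	1.98	1.51
chr14:36198687-36216226	unaffected	GM19141	2.06	2.63
chr14:69730226-69746414	unaffected	GM19141	5.76	5.81
chr14:72343297-72429399	unaffected	GM19099	1.83	2.39
chr14:72343297-72429399	unaffected	GM19141	3.30	2.29
chr14:99906106-99911812	unaffected	GM19099	2.49	2.41
chr15:22775434-22933834	unaffected	GM19099	11.24	9.95
chr15:22775434-22933834	unaffected	GM19141	7.06	8.26
chr15:28921438-28971039	unaffected	GM19099	11.73	7.79
chr15:28921438-28971039	unaffected	GM19141	2.13	2.70
chr15:89614733-89637888	unaffected	GM19099	2.88	2.74
chr16:53974720-54069307	unaffected	GM19099	5.38	2.88
chr16:53974720-54069307	unaffected	GM19141	1.10	1.64
chr16:83152950-83155553	unaffected	GM19141	3.52	3.6
chr17:6531791-6555012	unaffected	GM19141	3.75	3.89
chr17:34566422-34580691	unaffected	GM19099	2.65	2.28
chr17:34566422-34580691	unaffected	GM19141	1.56	1.78
chr17:63031387-63046267	unaffected	GM19099	3.08	2.46
chr17:63031387-63046267	unaffected	GM19141	1.59	1.83
chr18:26824546-26875293	unaffected	GM19099	1.88	2.21
chr18:26824546-26875293	unaffected	GM19141	4.83	3.67
chr18:42780796-42812910	unaffected	GM19099	1.97	1.83
chr18:42780796-42812910	unaffected	GM19141	2.41	2.60
chr19:40008284-40033757	unaffected	GM19099	6.05	5.53
chr19:40008284-40033757	unaffected	GM19141	4.29	4.95
chr19:56807457-56823545	unaffected	GM19099	1.45	1.24
chr19:56807457-56823545	unaffected	GM19141	3.84	5.51
chr19:58776466-58798723	unaffected	GM19099	3.02	3.32
chr22:22567862-22619365	unaffected	GM19099	1.12	1.03
chr22:22567862-22619365	unaffected	GM19141	8.09	10.02
chr22:43268050-43270537	unaffected	GM19099	1.46	1.75
chr22:43268050-43270537	unaffected	GM19141	3.74	2.97
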