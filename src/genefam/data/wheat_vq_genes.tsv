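name	gene_id	location	orf_length_bp	size_aa	mw_da	pi	exons
TaVQ1	TraesCS1A02G338700	Chr1A:528,102,140–528,103,155	2172	723	61,926.76	4.99	1
TaVQ2	TraesCS2A01G487800	Chr2A:722,518,069–722,518,557	489	162	16,310.14	8.11	1
TaVQ3	TraesCS2A01G517000	Chr2A:740,346,569–740,347,388	636	211	22,232.87	9.77	1
TaVQ4	TraesCS2B01G314600	Chr2B:449,669,843–449,671,002	990	329	34,759.36	9.97	1
TaVQ5	TraesCS2B01G515400	Chr2B:710,280,174–710,280,671	498	165	16,828.73	6.09	1
TaVQ6	TraesCS2B01G545500	Chr2B:742,454,459–742,455,094	636	211	22,348.05	9.87	1
TaVQ7	TraesCS2D01G296200	Chr2D:378,525,321–378,526,310	990	329	34,841.5	9.97	1
TaVQ8	TraesCS2D01G488100	Chr2D:587,696,143–587,696,631	489	162	16,649.49	6.92	1
TaVQ9	TraesCS2D01G518600	Chr2D:608,745,741–608,746,370	630	209	22,044.73	9.93	1
TaVQ10	TraesCS3A01G044200	Chr3A:23,866,681–23,867,710	771	256	26,516.25	6.49	1
TaVQ11	TraesCS3A01G190200	Chr3A:235,380,871–235,382,316	702	233	24,220.28	6.11	1
TaVQ12	TraesCS3A01G334400	Chr3A:580,608,595–580,609,062	468	155	15,944.31	5.77	1
TaVQ13	TraesCS3B01G197900	Chr3B:225,257,528–225,258,102	486	161	17,544.85	5.7	2
TaVQ14	TraesCS3B01G219100	Chr3B:262,901,818–262,902,606	789	262	27,481.07	9.16	1
TaVQ15	TraesCS3B01G365300	Chr3B:577,490,273–577,490,731	459	152	15,724.13	6.07	1
TaVQ16	TraesCS3B01G478300	Chr3B:726,621,717–726,622,121	405	134	14,557.72	10.15	1
TaVQ17	TraesCS3D01G036600	Chr3D:13,254,563–13,257,748	774	257	26,587.4	6.7	2
TaVQ18	TraesCS3D01G174600	Chr3D:156,240,964–156,246,686	489	162	17,816.12	5.45	2
TaVQ19	TraesCS3D01G193700	Chr3D:184,379,368–184,380,834	717	238	24,770.88	6.12	1
TaVQ20	TraesCS3D02G272900	Chr3D:378,529,151–378,530,444	2154	717	61,510.13	5.0	1
TaVQ21	TraesCS4A01G369400	Chr4A:641,502,472–641,502,912	441	146	14,995.88	11.33	1
TaVQ22	TraesCS4A01G411100	Chr4A:683,787,345–683,787,800	456	151	15,683.79	10.54	1
TaVQ23	TraesCS4A01G411200	Chr4A:683,800,842–683,801,246	405	134	14,461.68	10.61	1
TaVQ24	TraesCS4A01G411300	Chr4A:683,805,840–683,806,277	438	145	15,124.32	10.9	1
TaVQ25	TraesCS4B01G178500	Chr4B:391,157,880–391,158,956	438	145	14,849.46	7.1	1
TaVQ26	TraesCS4B01G311200	Chr4B:601,276,598–601,277,606	435	144	14,860.96	11.14	1
TaVQ27	TraesCS4B01G311300	Chr4B:601,284,457–601,284,921	465	154	16,000.23	10.55	1
TaVQ28	TraesCS4B01G311400	Chr4B:601,306,252–601,306,716	465	154	16,004.18	10.55	1
TaVQ29	TraesCS4D01G180100	Chr4D:313,885,547–313,886,431	450	149	15,190.79	8.01	1
TaVQ30	TraesCS4D02G021000	Chr4D:8,997,650–8,998,244	1002	333	26,481.38	5.19	1
TaVQ31	TraesCS5A01G010900	Chr5A:7,167,768–7,168,166	399	132	14,359.52	10.15	1
TaVQ32	TraesCS5A01G027100	Chr5A:22,485,164–22,486,133	759	252	26,758.28	9.44	1
TaVQ33	TraesCS5A01G189700	Chr5A:393,252,902–393,254,173	1272	423	42,945.76	6.55	1
TaVQ34	TraesCS5A01G427000	Chr5A:611,817,416–611,818,023	444	147	15,224.72	9.56	1
TaVQ35	TraesCS5B01G008700	Chr5B:9,243,595–9,244,008	414	137	14,803.08	9.88	1
TaVQ36	TraesCS5B01G026300	Chr5B:25,061,684–25,062,761	732	243	25,550.96	9.51	1
TaVQ37	TraesCS5B01G193500	Chr5B:349,712,051–349,713,313	1263	420	42,784.59	6.37	1
TaVQ38	TraesCS5B01G428900	Chr5B:604,226,071–604,227,208	444	147	15,152.49	9.56	1
TaVQ39	TraesCS5B01G503300	Chr5B:669,909,164–669,909,637	474	157	16,299.42	11.29	1
TaVQ40	TraesCS5D01G015700	Chr5D:9,068,493–9,069,444	399	132	14,358.51	10.15	1
TaVQ41	TraesCS5D01G034800	Chr5D:34,043,996–34,045,414	735	244	25,783.27	9.09	1
TaVQ42	TraesCS5D01G201200	Chr5D:304,876,446–304,878,167	1722	573	59,359.24	10.4	1
TaVQ43	TraesCS5D01G434900	Chr5D:490,166,006–490,166,449	444	147	15,110.47	9.56	1
TaVQ44	TraesCS6A01G156200	Chr6A:145,133,789–145,134,454	666	221	22,431.63	9.85	1
TaVQ45	TraesCS6A01G300700	Chr6A:533,466,786–533,467,235	450	149	15,970.96	10.16	1
TaVQ46	TraesCS6A01G301100	Chr6A:534,747,170–534,747,685	516	171	17,845.92	9.49	1
TaVQ47	TraesCS6B01G184400	Chr6B:207,154,528–207,155,778	681	226	23,005.3	10.08	1
TaVQ48	TraesCS6B01G330400	Chr6B:579,549,916–579,550,626	492	163	17,065.0	9.2	1
TaVQ49	TraesCS6D01G146200	Chr6D:116,952,516–116,953,190	675	224	22,649.97	9.85	1
TaVQ50	TraesCS6D01G280600	Chr6D:388,136,875–388,137,396	522	173	18,231.26	9.2	1
TaVQ51	TraesCS7A01G326900	Chr7A:475,165,941–475,166,708	768	255	26,443.91	10.07	1
TaVQ52	TraesCS7A01G349400	Chr7A:512,169,425–512,169,814	390	129	13,377.16	9.45	1
TaVQ53	TraesCS7A01G375900	Chr7A:549,001,358–549,001,981	603	200	21,229.86	10.61	2
TaVQ54	TraesCS7A01G401900	Chr7A:581,344,730–581,345,350	621	206	22,373.4	6.07	1
TaVQ55	TraesCS7A01G478700	Chr7A:671,483,204–671,483,848	645	214	21,698.87	9.51	1
TaVQ56	TraesCS7B01G227600	Chr7B:427,821,922–427,822,689	768	255	26,484.95	9.77	1
TaVQ57	TraesCS7B01G233400	Chr7B:436,838,688–436,839,071	384	127	13,522.39	8.91	1
TaVQ58	TraesCS7B01G277500	Chr7B:507,836,057–507,836,671	615	204	21,621.29	10.39	1
TaVQ59	TraesCS7B01G302000	Chr7B:538,864,067–538,864,690	624	207	22,455.42	5.97	1
TaVQ60	TraesCS7B01G381400	Chr7B:646,209,297–646,210,514	627	208	21,214.45	9.51	1
TaVQ61	TraesCS7D01G323700	Chr7D:413,441,710–413,442,474	765	254	26,249.67	9.63	1
TaVQ62	TraesCS7D01G329300	Chr7D:420,782,426–420,782,812	387	128	13,671.46	8.93	1
TaVQ63	TraesCS7D01G372400	Chr7D:481,836,636–481,837,615	477	158	16,567.59	10.19	1
TaVQ64	TraesCS7D01G395700	Chr7D:510,450,077–510,450,709	636	211	22,939.95	5.67	1
TaVQ65	TraesCS7D01G466100	Chr7D:579,961,244–579,961,867	624	207	21,039.19	9.3	1
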