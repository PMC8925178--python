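pair	ka	ks	ka_ks	date_mya
TaVQ1/TaVQ4	0.0127	0.1185	0.1070	9.1162
TaVQ1/TaVQ7	0.0070	0.0894	0.0790	6.8792
TaVQ3/TaVQ6	0.0240	0.0751	0.3200	5.7800
TaVQ3/TaVQ9	0.3823	0.2480	1.5420	19.0754
TaVQ4/TaVQ7	0.0085	0.0935	0.0900	7.1931
TaVQ6/TaVQ9	0.3781	0.2406	1.5720	18.5046
TaVQ10/TaVQ17	0.0448	0.0747	0.5990	5.7446
TaVQ11/TaVQ14	1.8069	0.9075	1.9910	69.8100
TaVQ11/TaVQ19	1.0034	0.6031	1.6640	46.3915
TaVQ12/TaVQ15	0.2352	0.1872	1.2560	14.4008
TaVQ13/TaVQ18	0.4955	0.3656	1.3550	28.1223
TaVQ14/TaVQ19	2.2662	0.9324	2.4310	71.7200
TaVQ21/TaVQ39	1.1545	0.9827	1.1750	75.5954
TaVQ22/TaVQ23	1.1107	0.9339	1.1890	71.8415
TaVQ22/TaVQ26	0.9021	0.8832	1.0210	67.9385
TaVQ22/TaVQ27	0.9769	0.8069	1.2110	62.0700
TaVQ22/TaVQ28	0.9796	0.8010	1.2230	61.6123
TaVQ22/TaVQ30	0.9757	0.8110	1.2030	62.3854
TaVQ24/TaVQ26	0.8192	0.8369	0.9790	64.3792
TaVQ24/TaVQ27	0.9598	0.8863	1.0830	68.1777
TaVQ24/TaVQ28	0.9475	0.8613	1.1000	66.2500
TaVQ24/TaVQ30	0.4472	0.4703	0.9510	36.1738
TaVQ26/TaVQ27	0.5848	0.5587	1.0470	42.9754
TaVQ26/TaVQ28	0.5786	0.5392	1.0730	41.4792
TaVQ26/TaVQ30	0.9816	0.9084	1.0810	69.8746
TaVQ27/TaVQ28	0.0059	0.0163	0.3640	1.2538
TaVQ27/TaVQ30	0.9130	0.8141	1.1210	62.6192
TaVQ27/TaVQ39	0.6100	0.4961	1.2300	38.1592
TaVQ28/TaVQ30	0.9005	0.7965	1.1310	61.2700
TaVQ28/TaVQ39	0.6039	0.4944	1.2210	38.0331
TaVQ32/TaVQ36	0.9418	0.5073	1.8560	39.0254
TaVQ32/TaVQ41	0.8366	0.6503	1.2860	50.0215
TaVQ33/TaVQ37	1.3991	1.0467	1.3370	80.5123
TaVQ33/TaVQ42	2.5055	1.2491	2.0060	96.0877
TaVQ36/TaVQ41	0.8192	0.6094	1.3440	46.8800
TaVQ37/TaVQ42	2.1547	1.5197	1.4180	116.8985
TaVQ44/TaVQ47	0.2084	0.1818	1.1470	13.9815
TaVQ44/TaVQ49	0.2361	0.1606	1.4700	12.3569
TaVQ47/TaVQ49	0.2438	0.1783	1.3670	13.7138
TaVQ51/TaVQ56	0.2983	0.3403	0.8770	26.1769
TaVQ51/TaVQ61	0.2983	0.3403	0.8770	26.1769
TaVQ53/TaVQ58	1.4092	0.5952	2.3680	45.7823
TaVQ54/TaVQ59	0.9133	0.4927	1.8540	37.8962
TaVQ55/TaVQ60	1.2444	0.5470	2.2750	42.0762
TaVQ55/TaVQ65	1.2015	0.4813	2.4960	37.0231
TaVQ56/TaVQ61	0.1112	0.1833	0.6060	14.1023
TaVQ59/TaVQ64	1.0923	0.6707	1.6290	51.5885
TaVQ60/TaVQ65	0.1719	0.1390	1.2370	10.6892
TaVQ1/OsVQ8	2.7423	0.8121	3.3770	62.4654
TaVQ1/OsVQ15	1.7626	1.1060	1.5940	85.0769
TaVQ3/OsVQ16	2.7350	0.8081	3.3840	62.1623
TaVQ4/OsVQ15	1.7960	1.0882	1.6500	83.7077
TaVQ6/OsVQ16	2.5321	0.8356	3.0300	64.2731
TaVQ7/OsVQ8	2.6174	0.8540	3.0650	65.6892
TaVQ7/OsVQ15	1.7711	1.1700	1.5140	89.9977
TaVQ9/OsVQ16	2.1032	0.7993	2.6310	61.4815
TaVQ10/OsVQ12	1.5611	0.9874	1.5810	75.9523
TaVQ17/OsVQ12	1.5725	1.0693	1.4710	82.2562
TaVQ26/OsVQ26	1.8812	1.6479	1.1420	126.7631
TaVQ32/OsVQ8	2.3258	0.8401	2.7680	64.6254
TaVQ33/OsVQ35	1.6720	0.9193	1.8190	70.7123
TaVQ36/OsVQ8	2.7247	1.0176	2.6780	78.2731
TaVQ37/OsVQ35	1.6260	0.8935	1.8200	68.7277
TaVQ41/OsVQ8	2.0860	0.9970	2.0920	76.6931
TaVQ44/OsVQ5	1.3857	0.6703	2.0670	51.5615
TaVQ47/OsVQ5	1.1333	0.6778	1.6720	52.1400
TaVQ49/OsVQ5	1.0462	0.5916	1.7680	45.5054
TaVQ53/OsVQ23	1.8754	0.6018	3.1160	46.2923
TaVQ58/OsVQ23	1.6660	0.5821	2.8620	44.7800
TaVQ63/OsVQ23	1.8612	0.7183	2.5910	55.2562
TaVQ1/ZmVQ14	1.7229	0.7294	2.3620	56.1085
TaVQ1/ZmVQ59	2.1932	0.9246	2.3720	71.1208
TaVQ4/ZmVQ14	1.8287	0.7525	2.4300	57.8877
TaVQ4/ZmVQ59	2.3077	0.9715	2.3750	74.7292
TaVQ6/ZmVQ13	1.9158	1.0257	1.8680	78.8962
TaVQ7/ZmVQ14	1.7985	0.7603	2.3660	58.4823
TaVQ7/ZmVQ59	2.3096	0.8740	2.6430	67.2292
TaVQ32/ZmVQ30	1.1674	0.8904	1.3110	68.4954
TaVQ41/ZmVQ30	2.1318	0.8361	2.5500	64.3131
TaVQ53/ZmVQ35	1.0682	0.6453	1.6550	49.6415
TaVQ53/ZmVQ51	2.1978	0.7752	2.8350	59.6277
TaVQ58/ZmVQ35	2.1378	0.8635	2.4760	66.4215
TaVQ58/ZmVQ51	1.3189	0.7664	1.7210	58.9500
TaVQ63/ZmVQ35	3.0729	0.7873	3.9030	60.5592
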