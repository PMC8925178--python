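gene_a	gene_b	kind
TaVQ1	TaVQ4	paralog
TaVQ1	OsVQ8	ortholog
TaVQ1	ZmVQ14	ortholog
TaVQ1	TaVQ7	paralog
TaVQ1	OsVQ15	ortholog
TaVQ1	ZmVQ59	ortholog
TaVQ3	TaVQ6	paralog
TaVQ3	OsVQ16	ortholog
TaVQ4	ZmVQ14	ortholog
TaVQ3	TaVQ9	paralog
TaVQ4	OsVQ15	ortholog
TaVQ4	ZmVQ59	ortholog
TaVQ4	TaVQ7	paralog
TaVQ6	OsVQ16	ortholog
TaVQ6	ZmVQ13	ortholog
TaVQ6	TaVQ9	paralog
TaVQ7	OsVQ8	ortholog
TaVQ7	ZmVQ14	ortholog
TaVQ10	TaVQ17	paralog
TaVQ7	OsVQ15	ortholog
TaVQ7	ZmVQ59	ortholog
TaVQ11	TaVQ14	paralog
TaVQ9	OsVQ16	ortholog
TaVQ32	ZmVQ30	ortholog
TaVQ11	TaVQ19	paralog
TaVQ10	OsVQ12	ortholog
TaVQ41	ZmVQ30	ortholog
TaVQ12	TaVQ15	paralog
TaVQ17	OsVQ12	ortholog
TaVQ53	ZmVQ35	ortholog
TaVQ13	TaVQ18	paralog
TaVQ26	OsVQ26	ortholog
TaVQ53	ZmVQ51	ortholog
TaVQ14	TaVQ19	paralog
TaVQ32	OsVQ8	ortholog
TaVQ58	ZmVQ35	ortholog
TaVQ21	TaVQ39	paralog
TaVQ33	OsVQ35	ortholog
TaVQ58	ZmVQ51	ortholog
TaVQ22	TaVQ23	paralog
TaVQ36	OsVQ8	ortholog
TaVQ63	ZmVQ35	ortholog
TaVQ22	TaVQ26	paralog
TaVQ37	OsVQ35	ortholog
TaVQ22	TaVQ27	paralog
TaVQ41	OsVQ8	ortholog
TaVQ22	TaVQ28	paralog
TaVQ44	OsVQ5	ortholog
TaVQ22	TaVQ30	paralog
TaVQ47	OsVQ5	ortholog
TaVQ24	TaVQ26	paralog
TaVQ49	OsVQ5	ortholog
TaVQ24	TaVQ27	paralog
TaVQ53	OsVQ23	ortholog
TaVQ24	TaVQ28	paralog
TaVQ58	OsVQ23	ortholog
TaVQ24	TaVQ30	paralog
TaVQ63	OsVQ23	ortholog
TaVQ26	TaVQ27	paralog
TaVQ26	TaVQ28	paralog
TaVQ26	TaVQ30	paralog
TaVQ27	TaVQ28	paralog
TaVQ27	TaVQ30	paralog
TaVQ27	TaVQ39	paralog
TaVQ28	TaVQ30	paralog
TaVQ28	TaVQ39	paralog
TaVQ32	TaVQ36	paralog
TaVQ32	TaVQ41	paralog
TaVQ33	TaVQ37	paralog
TaVQ33	TaVQ42	paralog
TaVQ36	TaVQ41	paralog
TaVQ37	TaVQ42	paralog
TaVQ44	TaVQ47	paralog
TaVQ44	TaVQ49	paralog
TaVQ47	TaVQ49	paralog
TaVQ51	TaVQ56	paralog
TaVQ51	TaVQ61	paralog
TaVQ53	TaVQ58	paralog
TaVQ54	TaVQ59	paralog
TaVQ55	TaVQ60	paralog
TaVQ55	TaVQ65	paralog
TaVQ56	TaVQ61	paralog
TaVQ59	TaVQ64	paralog
TaVQ60	TaVQ65	paralog
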