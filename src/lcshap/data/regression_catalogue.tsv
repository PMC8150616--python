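id	contig	start	end	length	observations	allele	spop_AFR	spop_EAS	spop_EUR	pop_CHB	pop_GBR	pop_LWK
HAP1	chr1	331	544	214	5	TOY*01	1	4	0	4	0	1
HAP2	chr1	331	619	289	4	TOY*01	2	2	0	2	0	2
HAP3	chr1	361	544	184	4	TOY*01	1	0	3	0	3	1
HAP4	chr1	21	544	524	2	TOY*02	0	0	2	0	2	0
HAP5	chr1	21	544	524	2	TOY*01	0	2	0	2	0	0
HAP6	chr1	131	579	449	2	TOY*01	0	0	2	0	2	0
HAP7	chr1	211	544	334	2	TOY*01	0	0	2	0	2	0
HAP8	chr1	251	699	449	2	TOY*01	0	2	0	2	0	0
HAP9	chr1	331	579	249	2	TOY*01	2	0	0	0	0	2
HAP10	chr1	361	619	259	2	TOY*01	1	0	1	0	1	1
HAP11	chr1	1	544	544	1	unclassified	0	0	1	0	1	0
HAP12	chr1	1	544	544	1	TOY*01	0	0	1	0	1	0
HAP13	chr1	91	579	489	1	unclassified	0	1	0	1	0	0
HAP14	chr1	91	579	489	1	TOY*01	0	1	0	1	0	0
HAP15	chr1	251	579	329	1	TOY*01	0	1	0	1	0	0
HAP16	chr1	251	579	329	1	TOY*01	0	1	0	1	0	0
HAP17	chr1	291	900	610	1	unclassified	1	0	0	0	0	1
HAP18	chr1	291	900	610	1	TOY*01	1	0	0	0	0	1
HAP19	chr1	331	544	214	1	TOY*01	1	0	0	0	0	1
HAP20	chr1	331	619	289	1	TOY*02	0	1	0	1	0	0
HAP21	chr1	331	619	289	1	TOY*01	0	1	0	1	0	0
HAP22	chr1	331	659	329	1	TOY*01	0	0	1	0	1	0
HAP23	chr1	331	659	329	1	TOY*01	0	0	1	0	1	0
HAP24	chr1	361	544	184	1	TOY*02	0	0	1	0	1	0
HAP25	chr1	361	544	184	1	TOY*01	1	0	0	0	0	1
HAP26	chr1	361	619	259	1	TOY*02	1	0	0	0	0	1
HAP27	chr1	361	619	259	1	TOY*01	0	0	1	0	1	0
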