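specimen_id	species	genus	n_alleles	size_min	size_max	avg_size	pct_q20	post_trim	coverage	full_length
4333	Aedeomyia venustipes	Aedeomyia	1	522	522	522	94.0	453	86.8	1
4560A	Aedeomyia venustipes	Aedeomyia	2	509	522	516	93.4	454	88.1	1
4560B	Aedeomyia venustipes	Aedeomyia	1	522	522	522	91.8	450	86.2	1
4309A	Anopheles annulipes	Anopheles	2	336	357	347	91.0	518	149.5	0
4309B	Anopheles annulipes	Anopheles	2	282	316	299	90.2	520	173.9	0
4309C	Anopheles annulipes	Anopheles	1	305	305	305	91.3	523	171.5	0
4315A	Coquillettidia linealis	Coquillettidia	4	454	485	468	90.1	413	88.3	1
4315B	Coquillettidia linealis	Coquillettidia	1	482	482	482	84.8	380	78.8	1
4332B	Coquillettidia linealis	Coquillettidia	1	483	483	483	83.2	380	78.7	1
4342	Culex annulirostris	Culex	1	442	442	442	80.9	323	73.1	1
4344	Culex annulirostris	Culex	2	444	446	445	70.3	251	56.4	1
4345	Culex annulirostris	Culex	3	442	447	444	67.1	251	56.6	1
4314B	Culex annulirostris	Culex	2	440	447	444	78.9	328	74.0	1
4324B	Culex annulirostris	Culex	4	438	449	442	80.5	277	62.6	1
4310A	Culex australicus	Culex	2	476	482	479	84.6	364	76.0	1
4310B	Culex australicus	Culex	3	470	478	474	85.3	370	78.0	1
4326A	Culex australicus	Culex	1	478	478	478	36.9	126	26.4	1
4326B	Culex australicus	Culex	3	478	486	482	87.4	391	81.1	1
4326C	Culex australicus	Culex	2	478	482	480	62.8	124	25.8	1
4348B	Culex cylindricus	Culex	5	378	432	410	92.6	366	89.3	1
4348C	Culex cylindricus	Culex	4	394	432	408	92.9	370	90.7	1
4348D	Culex cylindricus	Culex	7	394	432	418	91.2	361	86.3	1
4348E	Culex cylindricus	Culex	2	396	432	414	91.9	364	87.9	1
4682B	Culex palpalis	Culex	3	436	446	441	71.3	238	53.9	1
4683A	Culex palpalis	Culex	2	442	449	446	55.3	107	24.0	1
4312A	Culex pipiens form molestus	Culex	2	501	512	507	33.3	99	19.5	1
4312B	Culex pipiens form molestus	Culex	2	499	508	504	63.7	196	38.9	1
4339A	Culex pipiens form molestus	Culex	1	506	506	506	93.0	446	88.1	1
4339B	Culex pipiens form molestus	Culex	1	501	501	501	34.1	104	20.8	1
4318B	Culex quinquefasciatus	Culex	3	492	504	497	40.8	95	19.1	1
4318C	Culex quinquefasciatus	Culex	1	501	501	501	67.4	299	59.7	1
4318D	Culex quinquefasciatus	Culex	1	500	500	500	34.9	111	22.2	1
4318E	Culex quinquefasciatus	Culex	1	499	499	499	92.2	437	87.6	1
4903	Culiseta inconspicua	Culiseta	1	393	393	393	89.5	321	81.7	1
4904	Culiseta inconspicua	Culiseta	1	393	393	393	89.8	322	81.9	1
4329B	Dobrotworskyius alboannulatus	Dobrotworskyius	17	376	399	391	84.3	295	75.5	1
4331A	Dobrotworskyius alboannulatus	Dobrotworskyius	11	376	397	390	88.4	319	81.7	1
4331B	Dobrotworskyius alboannulatus	Dobrotworskyius	12	376	399	392	89.8	327	83.5	1
4331C	Dobrotworskyius alboannulatus	Dobrotworskyius	13	376	399	391	81.2	307	78.5	1
4681	Dobrotworskyius rubrithorax	Dobrotworskyius	24	318	404	379	62.6	172	45.4	1
4902	Dobrotworskyius rubrithorax	Dobrotworskyius	35	318	403	384	60.1	175	45.5	1
4327A	Dobrotworskyius rubrithorax	Dobrotworskyius	31	319	401	378	62.3	179	47.3	1
4327B	Dobrotworskyius rubrithorax	Dobrotworskyius	24	341	404	386	58.7	154	39.9	1
4551	Macleaya macmillani	Macleaya	2	433	434	434	90.7	362	83.5	1
4334	Macleaya tremula	Macleaya	2	410	410	410	88.7	337	82.2	1
4556	Macleaya tremula	Macleaya	2	411	433	422	73.4	309	73.2	1
4905	Macleaya tremula	Macleaya	1	410	410	410	90.1	342	83.4	1
4335	Macleaya wattensis	Macleaya	3	418	420	419	79.9	301	71.8	1
4558	Macleaya wattensis	Macleaya	2	416	426	421	88.3	347	82.4	1
4323	Mucidus alternans	Mucidus	1	392	392	392	58.9	216	55.1	1
4328A	Mucidus alternans	Mucidus	2	392	396	394	59.4	193	49.0	1
4328B	Mucidus alternans	Mucidus	2	392	396	394	78.2	285	72.3	1
4336A	Mucidus alternans	Mucidus	3	385	394	390	82.9	287	73.5	1
4336B	Mucidus alternans	Mucidus	3	356	396	381	77.3	276	72.4	1
4308A	Ochlerotatus bancroftianus	Ochlerotatus	2	480	482	481	82.0	365	75.9	1
4308B	Ochlerotatus bancroftianus	Ochlerotatus	3	480	491	484	90.0	408	84.4	1
4308C	Ochlerotatus bancroftianus	Ochlerotatus	4	475	491	483	47.6	130	26.9	1
4308D	Ochlerotatus bancroftianus	Ochlerotatus	4	478	491	485	88.1	397	81.9	1
4330	Ochlerotatus camptorhynchus	Ochlerotatus	2	383	387	385	88.4	327	84.9	1
4341	Ochlerotatus camptorhynchus	Ochlerotatus	3	372	387	378	89.9	324	85.8	1
4347	Ochlerotatus camptorhynchus	Ochlerotatus	3	368	387	378	90.1	317	83.8	1
4304B	Ochlerotatus camptorhynchus	Ochlerotatus	1	391	391	391	83.7	302	77.2	1
4303	Ochlerotatus mallochi	Ochlerotatus	5	418	437	428	89.0	370	86.4	1
4325	Ochlerotatus mallochi	Ochlerotatus	2	425	436	431	73.6	262	60.9	1
4553	Ochlerotatus mallochi	Ochlerotatus	2	425	436	431	89.2	359	83.4	1
4554	Ochlerotatus mallochi	Ochlerotatus	5	425	436	430	89.9	378	87.8	1
4555	Ochlerotatus mallochi	Ochlerotatus	5	425	436	430	86.0	356	82.7	1
4305A	Ochlerotatus sagax	Ochlerotatus	3	401	407	403	65.4	210	52.1	1
4305B	Ochlerotatus sagax	Ochlerotatus	4	400	411	406	65.2	213	52.5	1
4305C	Ochlerotatus sagax	Ochlerotatus	5	388	407	400	78.0	286	71.6	1
4305D	Ochlerotatus sagax	Ochlerotatus	5	400	410	405	66.2	209	51.6	1
4302A	Ochlerotatus theobaldi	Ochlerotatus	2	423	425	424	79.1	286	67.5	1
4302B	Ochlerotatus theobaldi	Ochlerotatus	3	411	428	419	78.4	310	73.9	1
4302C	Ochlerotatus theobaldi	Ochlerotatus	3	419	428	423	80.9	292	69.0	1
4302D	Ochlerotatus theobaldi	Ochlerotatus	2	419	426	423	81.9	302	71.5	1
4301A	Ochlerotatus vittiger	Ochlerotatus	2	406	410	408	89.7	337	82.6	1
4301B	Ochlerotatus vittiger	Ochlerotatus	2	406	408	407	80.8	286	70.3	1
4301C	Ochlerotatus vittiger	Ochlerotatus	4	406	414	410	80.1	282	68.9	1
4301D	Ochlerotatus vittiger	Ochlerotatus	2	406	414	410	70.0	212	51.7	1
4319A	Rampamyia notoscripta	Rampamyia	5	426	466	440	87.4	354	80.4	1
4319B	Rampamyia notoscripta	Rampamyia	7	365	464	427	50.7	123	28.8	1
4319C	Rampamyia notoscripta	Rampamyia	7	351	464	423	81.3	373	88.2	1
4337A	Rampamyia notoscripta	Rampamyia	6	339	434	412	82.3	332	80.6	1
4337B	Rampamyia notoscripta	Rampamyia	6	412	464	435	84.4	336	77.3	1
4313	Tripteroides atripes	Tripteroides	2	356	359	358	86.8	273	76.4	1
4320	Tripteroides atripes	Tripteroides	2	356	359	358	84.4	260	72.7	1
4316A	Tripteroides sp.	Tripteroides	3	354	364	360	80.8	240	66.7	1
4349	Tripteroides tasmaniensis	Tripteroides	1	376	376	376	83.7	287	76.3	1
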