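# Published annotation table, transcribed verbatim (coordinates 1-based inclusive).
genome_id	kind	name	strand	start	end	declared_length	start_codon	stop_codon	pctA	pctC	pctG	pctT
XV	tRNA	trnF	H	1	68	68			36.8	22.1	23.5	17.6
XV	rRNA	rrnS	H	69	1016	948			32.3	25.9	19.6	22.2
XV	tRNA	trnV	H	1017	1085	69			33.3	23.2	14.5	29.0
XV	rRNA	rrnL	H	1086	2720	1635			37.1	21.4	17.7	23.8
XV	tRNA	trnL-UUR	H	2722	2796	75			21.3	29.3	25.3	24.1
XV	gene	nad1	H	2801	3769	969	ATG	TAG	30.5	26.5	12.4	30.6
XV	tRNA	trnI	H	3769	3839	71			31.0	22.5	22.5	24.0
XV	tRNA	trnQ	L	3840	3909	70			20.0	14.3	13.4	52.3
XV	tRNA	trnM	H	3909	3977	69			31.9	26.1	14.5	27.5
XV	gene	nad2	H	3978	5015	1038	ATG	TAG	32.2	27.5	9.3	31.0
XV	tRNA	trnW	H	5014	5082	69			36.2	21.7	17.4	24.7
XV	tRNA	trnA	L	5084	5154	71			28.2	12.7	23.9	35.2
XV	tRNA	trnN	L	5154	5228	75			24.0	16.0	30.7	29.3
XV	tRNA	trnC	L	5260	5325	66			24.2	22.7	30.3	22.8
XV	tRNA	trnY	L	5326	5397	72			22.2	22.2	29.2	26.4
XV	gene	cox1	H	5397	6953	1557	GTG	TAA	28.5	23.3	16.1	32.1
XV	tRNA	trnS-UCN	L	6956	7026	71			28.2	25.4	16.9	29.5
XV	tRNA	trnD	H	7042	7109	68			38.9	22.1	19.1	19.9
XV	gene	cox2	H	7112	7799	688	ATG	T	32.3	25.0	14.2	28.5
XV	tRNA	trnK	H	7800	7874	75			29.3	22.7	12.7	35.3
XV	gene	atp8	H	7876	8043	168	ATG	TAA	36.9	28.0	8.3	26.8
XV	gene	atp6	H	8034	8717	684	ATG	TAA	29.1	27.0	10.5	33.4
XV	gene	cox3	H	8717	9500	784	ATG	T	28.6	25.8	15.8	29.8
XV	tRNA	trnG	H	9501	9570	70			35.7	18.6	15.7	30.0
XV	gene	nad3	H	9571	9913	343	ATG	T	25.1	28.6	12.8	33.5
XV	tRNA	trnR	H	9914	9983	70			35.7	18.6	15.7	30.0
XV	gene	nad4L	H	9983	10279	297	ATG	TAA	26.6	27.3	13.1	33.0
XV	gene	nad4	H	10273	11650	1378	ATG	T	31.8	26.1	11.1	31.0
XV	tRNA	trnH	H	11651	11719	69			34.8	17.4	17.4	30.4
XV	tRNA	trnS-AGY	H	11719	11785	67			22.4	23.9	23.9	29.8
XV	tRNA	trnL-CUN	H	11785	11858	74			32.4	20.3	21.6	25.7
XV	gene	nad5	H	11859	13676	1818	ATG	TAA	32.3	24.4	11.7	31.6
XV	gene	nad6	L	13668	14186	519	ATG	TAA	19.8	9.4	28.7	42.1
XV	tRNA	trnE	L	14187	14257	71			23.9	14.1	25.4	36.6
XV	gene	cytb	H	14258	15400	1143	ATG	TAG	28.6	26.2	13.1	32.1
XV	tRNA	trnT	H	15400	15471	72			29.2	25.0	20.8	25.0
XV	tRNA	trnP	L	15497	15563	67			23.9	10.4	28.4	37.3
XV	control_region	D-loop	H	15564	17716	2153			39.3	19.0	9.1	32.6
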