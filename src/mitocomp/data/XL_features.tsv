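# Published annotation table, transcribed verbatim (coordinates 1-based inclusive).
genome_id	kind	name	strand	start	end	declared_length	start_codon	stop_codon	pctA	pctC	pctG	pctT
XL	tRNA	trnF	H	1	69	69			33.3	23.2	24.6	18.9
XL	rRNA	rrnS	H	70	888	819			32.5	25.5	19.9	22.1
XL	tRNA	trnV	H	889	957	69			34.8	24.6	13.0	27.6
XL	rRNA	rrnL	H	958	2588	1631			36.4	21.0	17.7	24.9
XL	tRNA	trnL-UUR	H	2589	2663	75			24.0	26.7	24.0	25.3
XL	gene	nad1	H	2664	3635	972	ATG	TAG	31.6	24.9	12.3	31.2
XL	tRNA	trnI	H	3635	3705	71			31.0	21.1	22.5	25.4
XL	tRNA	trnQ	L	3705	3775	71			21.1	14.1	31.0	33.8
XL	tRNA	trnM	H	3775	3843	69			31.9	26.1	14.5	27.5
XL	gene	nad2	H	3844	4881	1038	ATG	TAG	31.8	26.9	10.2	31.1
XL	tRNA	trnW	H	4880	4948	69			36.2	28.3	18.8	16.7
XL	tRNA	trnA	L	4951	5019	69			30.4	13.0	20.3	36.3
XL	tRNA	trnN	L	5021	5091	71			23.9	15.5	28.2	32.4
XL	tRNA	trnC	L	5190	5259	70			25.8	22.7	28.8	22.7
XL	tRNA	trnY	L	6817	6887	71			21.4	20.0	31.4	27.2
XL	gene	cox1	H	5262	6816	1555	ATG	AAT	28.6	22.4	16.5	32.5
XL	tRNA	trnS-UCN	L	6817	6887	71			26.8	16.9	28.2	28.1
XL	tRNA	trnD	H	6903	6971	69			31.9	21.7	23.2	23.2
XL	gene	cox2	H	6974	7661	688	ATG	T	32.1	24.4	14.7	28.8
XL	tRNA	trnK	H	7662	7736	75			32.0	24.0	20.0	24.0
XL	gene	atp8	H	7738	7905	168	ATG	TAA	38.1	28.0	8.3	25.6
XL	gene	atp6	H	7896	8576	681	ATG	TAA	30.2	25.4	10.4	34.0
XL	gene	cox3	H	8576	9356	781	ATG	T	29.8	24.2	15.7	30.3
XL	tRNA	trnG	H	9357	9426	70			27.1	18.6	14.3	40.0
XL	gene	nad3	H	9427	9769	343	ATG	TAA	26.2	26.2	13.7	33.9
XL	tRNA	trnR	H	9770	9838	69			34.8	18.4	15.9	30.9
XL	gene	nad4L	H	9839	10135	297	ATG	TAA	30.3	23.9	12.8	33.0
XL	gene	nad4	H	10129	11512	1384	ATG	T	32.7	24.6	11.1	31.6
XL	tRNA	trnH	H	11513	11580	68			35.3	17.6	16.2	30.9
XL	tRNA	trnS-AGY	H	11581	11645	65			23.1	24.6	21.5	30.8
XL	tRNA	trnL-CUN	H	11646	11719	74			33.8	20.3	21.6	24.3
XL	gene	nad5	H	11720	13534	1815	ATG	TAA	33.2	23.3	11.5	32.0
XL	gene	nad6	L	13530	14042	513	ATG	AGA	19.9	9.4	28.1	42.6
XL	tRNA	trnE	L	14043	14111	69			24.6	14.5	26.1	34.8
XL	gene	cytb	H	14114	15253	1140	ATG	TAG	29.5	25.4	12.6	32.5
XL	tRNA	trnT	H	15253	15322	70			30.0	22.9	20.0	27.1
XL	tRNA	trnP	L	15350	15418	69			21.7	11.6	38.4	28.3
XL	control_region	D-loop	H	15419	17552	2134			39.3	17.9	9.4	33.4
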