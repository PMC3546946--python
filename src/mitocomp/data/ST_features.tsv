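# Published annotation table, transcribed verbatim (coordinates 1-based inclusive).
genome_id	kind	name	strand	start	end	declared_length	start_codon	stop_codon	pctA	pctC	pctG	pctT
ST	tRNA	trnF	H	1	68	68			38.2	22.1	22.1	17.6
ST	rRNA	rrnS	H	69	1011	943			32.7	27.8	20.0	19.5
ST	tRNA	trnV	H	1012	1081	70			32.9	28.6	14.3	24.2
ST	rRNA	rrnL	H	1082	2716	1635			34.9	24.1	18.5	22.5
ST	tRNA	trnL-UUR	H	2717	2791	75			25.3	25.3	22.7	26.7
ST	gene	nad1	H	2792	3759	968	ATG	TAG	28.0	30.0	13.7	28.3
ST	tRNA	trnI	H	3760	3830	71			28.2	23.9	25.4	22.5
ST	tRNA	trnQ	L	3830	3900	71			21.1	14.1	31.0	33.8
ST	tRNA	trnM	H	3900	3968	69			31.9	24.6	14.5	29.0
ST	gene	nad2	H	3969	5004	1036	ATG	TAG	29.5	33.3	9.7	27.5
ST	tRNA	trnW	H	5005	5073	69			33.3	23.2	23.2	20.3
ST	tRNA	trnA	L	5077	5145	69			29.0	13.0	21.7	36.3
ST	tRNA	trnN	L	5147	5219	73			24.7	17.8	26.0	31.5
ST	tRNA	trnC	L	5258	5323	66			25.8	22.7	31.8	19.7
ST	tRNA	trnY	L	5324	5393	70			20.0	22.9	31.4	25.7
ST	gene	cox1	H	5395	6951	1557	GTG	TAA	27.3	25.1	17.5	30.1
ST	tRNA	trnS-UCN	L	6954	7024	71			25.4	15.5	28.2	30.9
ST	tRNA	trnD	H	7040	7108	69			37.3	26.1	18.8	17.8
ST	gene	cox2	H	7111	7798	688	ATG	T	31.4	28.2	15.1	25.3
ST	tRNA	trnK	H	7799	7872	74			31.1	28.4	21.6	18.9
ST	gene	atp8	H	7874	8041	168	ATG	TAA	37.5	29.2	9.5	23.8
ST	gene	atp6	H	8032	8714	683	ATG	TAA	25.3	33.2	11.4	30.1
ST	gene	cox3	H	8715	9498	784	ATG	T	26.5	30.2	16.2	27.1
ST	tRNA	trnG	H	9499	9568	70			38.6	21.4	14.3	25.7
ST	gene	nad3	H	9569	9911	343	ATG	AAT	24.8	30.6	14.3	30.3
ST	tRNA	trnR	H	9912	9980	69			33.3	24.6	17.4	24.7
ST	gene	nad4L	H	9981	10277	297	ATG	TAA	23.9	33.0	15.5	27.6
ST	gene	nad4	H	10271	11648	1378	ATG	T	29.0	31.5	11.5	28.0
ST	tRNA	trnH	H	11649	11717	69			36.2	20.3	15.9	27.6
ST	tRNA	trnS-AGY	H	11718	11785	68			23.5	27.9	25.0	23.6
ST	tRNA	trnL-CUN	H	11786	11858	73			32.9	21.9	20.5	24.7
ST	gene	nad5	H	11859	13676	1818	ATG	TAA	30.5	30.2	12.7	26.6
ST	gene	nad6	L	13668	14186	519	ATG	TAA	15.2	10.4	35.1	39.3
ST	tRNA	trnE	L	14187	14255	69			26.1	14.5	26.1	33.3
ST	gene	cytb	H	14258	15400	1143	ATG	TAG	27.4	30.4	14.4	27.8
ST	tRNA	trnT	H	15400	15470	71			26.8	26.8	22.5	23.9
ST	tRNA	trnP	L	15500	15566	67			22.4	11.9	29.9	35.8
ST	control_region	D-loop	H	15567	17610	2044			39.0	20.2	10.7	30.1
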