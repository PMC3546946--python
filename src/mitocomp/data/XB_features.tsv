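# Published annotation table, transcribed verbatim (coordinates 1-based inclusive).
genome_id	kind	name	strand	start	end	declared_length	start_codon	stop_codon	pctA	pctC	pctG	pctT
XB	tRNA	trnF	H	1	68	68			36.8	22.1	23.5	17.6
XB	rRNA	rrnS	H	69	1015	947			32.2	25.0	19.6	23.2
XB	tRNA	trnV	H	1016	1085	70			32.9	24.3	14.3	28.5
XB	rRNA	rrnL	H	1086	2720	1635			36.5	19.6	18.2	25.7
XB	tRNA	trnL-UUR	H	2721	2795	75			25.3	26.7	22.7	25.3
XB	gene	nad1	H	2796	3764	969	ATG	TAG	29.1	21.3	15.3	34.3
XB	tRNA	trnI	H	3764	3834	71			31.0	21.1	22.5	25.4
XB	tRNA	trnQ	L	3834	3904	71			21.1	12.7	31.0	35.2
XB	tRNA	trnM	H	3904	3972	69			33.3	23.2	14.5	29.0
XB	gene	nad2	H	3973	5010	1038	ATG	TAG	31.5	24.2	11.4	32.9
XB	tRNA	trnW	H	5009	5077	69			36.2	20.3	17.4	26.1
XB	tRNA	trnA	L	5084	5154	71			31.0	11.3	19.7	38.0
XB	tRNA	trnN	L	5154	5228	75			25.3	20.0	26.7	28.0
XB	tRNA	trnC	L	5255	5320	66			24.2	25.8	28.8	21.2
XB	tRNA	trnY	L	5321	5392	72			23.6	26.4	27.8	22.2
XB	gene	cox1	H	5392	6948	1557	GTG	TAA	28.1	21.1	17.3	33.5
XB	tRNA	trnS-UCN	L	6950	7020	71			28.2	18.3	25.4	28.1
XB	tRNA	trnD	H	7031	7099	69			37.7	15.9	14.5	31.9
XB	gene	cox2	H	7102	7789	688	ATG	T	32.3	21.9	14.8	31.0
XB	tRNA	trnK	H	7790	7863	74			29.7	25.7	23.0	21.6
XB	gene	atp8	H	7865	8032	168	ATG	TAA	37.5	26.2	8.3	28.0
XB	gene	atp6	H	8023	8706	684	ATG	TAA	28.8	24.3	11.5	35.4
XB	gene	cox3	H	8706	9489	784	ATG	T	26.4	22.8	17.3	33.5
XB	tRNA	trnG	H	9490	9559	70			35.7	21.4	14.3	28.6
XB	gene	nad3	H	9560	9902	343	ATG	T	24.5	22.4	16.9	36.2
XB	tRNA	trnR	H	9903	9972	70			35.7	21.4	15.7	27.2
XB	gene	nad4L	H	9972	10268	297	ATG	TAA	26.6	24.6	13.8	35.0
XB	gene	nad4	H	10262	11639	1378	ATG	T	30.5	25.1	11.5	32.9
XB	tRNA	trnH	H	11640	11708	69			30.4	15.9	20.3	33.4
XB	tRNA	trnS-AGY	H	11708	11774	67			22.4	23.9	23.9	29.8
XB	tRNA	trnL-CUN	H	11774	11847	74			32.4	16.2	23.0	28.4
XB	gene	nad5	H	11848	13665	1818	ATG	TAA	31.4	23.7	12.6	32.3
XB	gene	nad6	L	13657	14175	519	ATG	TAA	19.5	11.9	29.5	39.1
XB	tRNA	trnE	L	14176	14245	70			28.6	11.4	21.4	38.6
XB	gene	cytb	H	14246	15388	1143	ATG	TAG	27.7	23.3	14.8	34.2
XB	tRNA	trnT	H	15388	15458	71			26.8	25.4	21.1	26.7
XB	tRNA	trnP	L	15499	15565	67			20.9	11.9	31.3	35.9
XB	control_region	D-loop	H	15566	17474	1909			37.2	19.0	9.8	34.0
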