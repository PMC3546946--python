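# Published sequencing-run statistics.
genome_id	total_reads	mapped_reads	total_nt	mapped_nt	genome_length
XB	499995	489725	172077728	171646577	17474
XV	9864	6627	8500481	3432828	17716
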