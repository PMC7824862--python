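phage_id	genome_length	taxon	morphology	gene_id	start	end	strand	product	protein_length	is_trna
TOY1	5000	Toyphage gamma		g001	1	300	+	terminase	99	False
TOY1	5000	Toyphage gamma		g002	400	900	-	lysozyme	166	False
TOY1	5000	Toyphage gamma		t001	950	1020	+	tRNA-Leu	1	True
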