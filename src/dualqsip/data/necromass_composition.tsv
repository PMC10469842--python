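necromass_type	pct_c	pct_n	fraction	pct_initial_mass	pct_initial_c	pct_initial_n	printed_fraction_cn
high	55.4	1.9	cell_soluble	17.7	18.0	54.5	9.6
high	55.4	1.9	non_hydrolyzable	42.4	24.9	15.6	46.4
low	50.7	2.9	cell_soluble	32.4	29.0	58.2	8.9
low	50.7	2.9	non_hydrolyzable	33.1	10.3	7.6	24.1
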