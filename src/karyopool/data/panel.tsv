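# Quantitative-analysis panel: the ten populations with more than 10
# specimens, with their printed polymorphism indices.  The n column is the
# larva count of the frequency table header (for YAR-RY this is the larger,
# previously published count of 100; the collection-sites table records 4).
population	n	pct_het_larvae	het_inv_per_larva	n_sequences	n_genotypes	b_chromosome_freq
YAR-RY	100	0	0	7	7	0
NSK-BE	45	44.4	0.467	9	10	0
NSK-KA	34	58.8	0.676	9	10	0
NSK-SH	259	60.6	0.684	12	14	0.050
NSK-2R	14	50.0	0.572	9	9	0
NSK-LI	32	73.1	0.937	9	11	0
NSK-OR	52	50.0	0.596	9	10	0.038
NSK-YU	151	52.3	0.576	9	11	0
NSK-ST	54	59.3	0.685	10	11	0
KHA-EV	36	2.8	0.028	8	8	0
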