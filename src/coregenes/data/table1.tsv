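clade	rank	alpha_diversity	n_genomes	n_core_families	n_S_cogs	jkl_enriched	jkl_percent	o_enriched	o_percent
Bacteroidetes/Chlorobi	group	5.2	48	3	0	0	33.3	0	38.6
Cyanobacteria	phylum	2.2	39	61	0	0	39.5	1	20.5
Proteobacteria	phylum	17.5	472	0	0	0	0.0	0	0.0
Firmicutes	phylum	10.8	233	1	0	0	100.0	0	0.0
Actinobacteria	phylum	5.9	110	1	0	0	0.0	1	100.0
Euryarchaeota	phylum	7.1	60	1	0	0	0.0	0	0.0
Bacteroidetes	phylum	4.5	37	7	0	1	55.8	0	28.7
Gammaproteobacteria	class	6.0	247	2	0	1	100.0	0	0.0
Actinobacteria	class	5.9	110	1	0	0	0.0	1	100.0
Clostridia	class	6.8	72	2	0	1	100.0	0	0.0
Alphaproteobacteria	class	5.4	109	0	0	0	0.0	0	0.0
Betaproteobacteria	class	2.3	48	70	0	1	55.6	0	8.2
Deltaproteobacteria	class	3.4	35	13	0	1	37.4	1	12.3
Epsilonproteobacteria	class	2.1	32	56	0	1	54.4	0	5.5
Bacilli	class	4.9	161	6	0	1	83.3	0	16.7
Actinobacteridae	subclass	5.0	102	2	0	0	32.7	0	67.3
Bacillales	order	2.8	79	28	0	1	45.4	1	14.2
Clostridiales	order	5.0	50	2	0	1	100.0	0	0.0
Lactobacillales	order	3.1	82	35	0	1	76.3	0	12.1
Actinomycetales	order	4.6	90	3	0	1	48.2	0	51.2
Rhizobiales	order	1.9	46	27	0	1	38.5	0	9.9
Pseudomonadales	order	1.0	31	159	0	1	44.5	0	6.8
Rickettsiales	order	1.9	30	16	0	1	53.6	0	0.0
Enterobacteriales	order	1.3	109	13	0	1	57.2	0	14.3
Streptococcaceae	family	1.8	52	316	11	1	46.1	0	5.9
Bacillaceae	family	1.9	42	217	3	1	33.4	1	7.2
Clostridiaceae	family	2.4	31	76	0	1	53.1	1	9.7
Enterobacteriaceae	family	1.3	109	10	0	1	56.8	0	14.4
Corynebacterineae	family	1.3	37	236	8	1	43.3	0	8.7
Streptococcus	genus	1.6	48	379	21	1	43.2	0	4.9
Bacillus	genus	1.5	32	334	6	1	28.9	1	6.5
Escherichia	genus	0.03	30	2192	23	1	17.8	1	4.7
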