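# Per-species NLR architecture counts and assembled-transcriptome sizes for
# seven conifers (two spruces, two pines, a fir, a larch, an arborvitae),
# transcribed from the published census table of the study this package
# reproduces.  One extraction-damaged digit (Picea mariana NB_RNL-(LRR)) is
# restored to 14 so the RNL block sums to its printed total of 43; all other
# cells verify against the printed row and column totals.
row	Abies_balsamea	Larix_laricina	Picea_glauca	Picea_mariana	Pinus_banksiana	Pinus_strobus	Thuja_occidentalis
transcriptome_size	46178	50712	37491	58751	47473	45447	38767
NB_CNL-(LRR)	65	146	115	166	82	103	51
NB_CNL2-(LRR)	47	18	17	17	36	21	34
RPW8	5	5	6	13	8	12	3
NB_RNL-(LRR)	11	8	6	14	21	12	13
RPW8-NB_RNL-(LRR)	16	33	19	16	26	16	15
TIR	43	100	121	144	94	89	72
NB_TNL-(LRR)	52	97	99	128	104	122	91
TIR-NB_TNL-(LRR)	55	143	58	105	52	126	154
TIR-LRR	0	3	1	2	0	2	0
Atypical	15	26	8	14	7	14	14
Undetermined	29	54	56	106	56	43	39
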