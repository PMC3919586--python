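# loop closure penalties, kcal/mol; sizes beyond the table reuse the last entry
kind	size	kcal
hairpin	3	5.0
hairpin	4	4.5
hairpin	5	4.5
hairpin	6	4.6
hairpin	7	4.7
hairpin	8	4.8
hairpin	9	4.9
hairpin	10	5.0
hairpin	11	5.1
hairpin	12	5.2
hairpin	13	5.3
hairpin	14	5.4
hairpin	15	5.5
hairpin	16	5.6
hairpin	17	5.7
hairpin	18	5.8
hairpin	19	5.9
hairpin	20	6.0
hairpin	21	6.1
hairpin	22	6.2
hairpin	23	6.3
hairpin	24	6.4
hairpin	25	6.5
hairpin	26	6.6
hairpin	27	6.7
hairpin	28	6.8
hairpin	29	6.9
hairpin	30	7.0
internal	1	2.9
internal	2	3.3
internal	3	3.7
internal	4	4.1
internal	5	4.5
internal	6	4.9
internal	7	5.3
internal	8	5.7
internal	9	6.0
internal	10	6.0
internal	11	6.0
internal	12	6.0
internal	13	6.0
internal	14	6.0
internal	15	6.0
internal	16	6.0
internal	17	6.0
internal	18	6.0
internal	19	6.0
internal	20	6.0
internal	21	6.0
internal	22	6.0
internal	23	6.0
internal	24	6.0
internal	25	6.0
internal	26	6.0
internal	27	6.0
internal	28	6.0
internal	29	6.0
internal	30	6.0
multiloop	0	3.0
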