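species	species_pmol_c171	species_pmol_nl	species_pmol_fa_sum	fa1	fa2	subspecies_pmol	subspecies_pct
pPC 30:0	28.2	16.4	19.3	16:0	14:0	19.3	100.0
pPC 30:1	0.0	4.9	3.1	16:1	14:0	3.1	100.0
pPC 32:0	79.0	60.8	82.3	18:0	14:0	2.3	2.8
pPC 32:0	79.0	60.8	82.3	16:0	16:0	80.0	97.2
pPC 32:1	205.9	188.2	194.0	18:1	14:0	10.3	5.3
pPC 32:1	205.9	188.2	194.0	16:0	16:1	183.6	94.7
pPC 32:2	14.7	12.7	12.5	18:2	14:0	0.8	6.7
pPC 32:2	14.7	12.7	12.5	16:0	16:2	3.8	31.4
pPC 32:2	14.7	12.7	12.5	16:1	16:1	7.8	61.9
pPC 34:1	760.3	677.6	706.5	20:1	14:0	0.4	0.1
pPC 34:1	760.3	677.6	706.5	18:0	16:1	20.0	2.9
pPC 34:1	760.3	677.6	706.5	18:1	16:0	686.1	97.1
pPC 34:2	137.9	89.5	96.7	18:1	16:1	55.6	57.3
pPC 34:2	137.9	89.5	96.7	18:2	16:0	41.0	42.7
pPC 34:3	2.3	7.6	20.5	20:3	14:0	10.9	51.8
pPC 34:3	2.3	7.6	20.5	18:1	16:2	1.7	8.8
pPC 34:3	2.3	7.6	20.5	18:2	16:1	3.7	18.9
pPC 34:3	2.3	7.6	20.5	18:3	16:0	4.1	20.5
pPC 34:4	0.0	2.8	25.6	20:4	14:0	25.6	100.0
pPC 36:1	110.2	73.5	91.8	20:1	16:0	14.2	15.5
pPC 36:1	110.2	73.5	91.8	18:0	18:1	77.7	84.5
pPC 36:2	178.2	125.1	133.6	20:1	16:1	4.3	3.3
pPC 36:2	178.2	125.1	133.6	20:2	16:0	7.1	5.5
pPC 36:2	178.2	125.1	133.6	18:0	18:2	12.9	9.7
pPC 36:2	178.2	125.1	133.6	18:1	18:1	109.3	81.6
pPC 36:3	62.5	48.4	48.5	20:2	16:1	1.7	3.5
pPC 36:3	62.5	48.4	48.5	20:3	16:0	27.0	55.6
pPC 36:3	62.5	48.4	48.5	18:0	18:3	1.5	3.1
pPC 36:3	62.5	48.4	48.5	18:1	18:2	18.3	37.8
pPC 36:4	117.1	85.4	71.7	22:4	14:0	3.9	5.2
pPC 36:4	117.1	85.4	71.7	20:3	16:1	2.8	4.1
pPC 36:4	117.1	85.4	71.7	20:4	16:0	60.9	84.9
pPC 36:4	117.1	85.4	71.7	18:1	18:3	3.4	4.8
pPC 36:4	117.1	85.4	71.7	18:2	18:2	0.7	1.1
pPC 36:5	22.0	19.2	12.5	22:5	14:0	0.9	7.5
pPC 36:5	22.0	19.2	12.5	20:4	16:1	3.1	24.8
pPC 36:5	22.0	19.2	12.5	20:5	16:0	8.5	67.7
pPC 38:2	32.8	17.5	25.2	22:0	16:1	6.6	26.2
pPC 38:2	32.8	17.5	25.2	22:2	16:0	3.4	13.4
pPC 38:2	32.8	17.5	25.2	20:1	18:1	12.6	50.0
pPC 38:2	32.8	17.5	25.2	20:2	18:0	2.6	10.3
pPC 38:3	19.3	17.1	20.7	22:3	16:0	3.8	18.3
pPC 38:3	19.3	17.1	20.7	20:1	18:2	1.4	6.9
pPC 38:3	19.3	17.1	20.7	20:2	18:1	5.1	24.9
pPC 38:3	19.3	17.1	20.7	20:3	18:0	10.3	49.9
pPC 38:4	56.0	40.6	38.1	22:4	16:0	9.8	25.5
pPC 38:4	56.0	40.6	38.1	20:2	18:2	0.2	0.6
pPC 38:4	56.0	40.6	38.1	20:3	18:1	10.8	28.5
pPC 38:4	56.0	40.6	38.1	20:4	18:0	17.4	45.5
pPC 38:5	70.1	57.3	48.1	22:4	16:1	2.1	4.4
pPC 38:5	70.1	57.3	48.1	22:5	16:0	23.8	49.1
pPC 38:5	70.1	57.3	48.1	20:3	18:2	0.5	1.0
pPC 38:5	70.1	57.3	48.1	20:4	18:1	18.1	39.0
pPC 38:5	70.1	57.3	48.1	20:5	18:0	3.6	7.4
pPC 38:6	56.9	42.5	28.6	22:5	16:1	3.0	10.2
pPC 38:6	56.9	42.5	28.6	22:6	16:0	19.9	69.8
pPC 38:6	56.9	42.5	28.6	20:4	18:2	2.1	7.5
pPC 38:6	56.9	42.5	28.6	20:5	18:1	3.6	12.6
pPC 40:2	33.8	16.9	29.2	24:1	16:1	4.8	16.4
pPC 40:2	33.8	16.9	29.2	22:0	18:2	1.4	4.9
pPC 40:2	33.8	16.9	29.2	22:1	18:1	23.0	78.8
pPC 40:5	27.2	13.7	15.4	22:3	18:2	0.2	1.3
pPC 40:5	27.2	13.7	15.4	22:4	18:1	5.9	37.6
pPC 40:5	27.2	13.7	15.4	22:5	18:0	7.3	47.7
pPC 40:5	27.2	13.7	15.4	20:1	20:4	2.0	13.4
pPC 40:6	25.6	15.8	17.2	22:5	18:1	11.6	66.6
pPC 40:6	25.6	15.8	17.2	22:6	18:0	5.6	33.4
pPC 40:7	8.8	7.4	9.0	22:5	18:2	0.9	9.8
pPC 40:7	8.8	7.4	9.0	22:6	18:1	7.4	82.5
pPC 40:7	8.8	7.4	9.0	20:3	20:4	0.7	7.8
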