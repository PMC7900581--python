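lipid_class	control_pmol	lppc160_pmol	lppc_o160_pmol
LPC	170.7	96.1	64.0
LPC O	39.1	27.6	21.4
LPE	1250.0	228.3	202.1
PC	7257.4	5439.7	3026.5
PC O	731.8	734.8	1240.1
PE	1991.1	1511.3	1192.6
PE O	83.5	253.7	335.9
SM	1437.1	1324.4	1290.1
pPC	0.0	1728.1	519.7
pPC O	0.0	15.8	3511.7
pSM	0.0	274.8	200.4
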