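# PepNovo-style output (DNMSO frozen dialect exemplar)
#Index	RnkScr	PnvScr	N-Gap	C-Gap	Charge	Sequence
>> 0 example.0
1	0.8230	45.10	0.0	0.0	2	PEPTIDE
2	0.4000	30.20	100.0	0.0	2	AG
>> 1 example.1
1	0.9100	77.70	0.0	128.09496	2	M[MOD:00719]K
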