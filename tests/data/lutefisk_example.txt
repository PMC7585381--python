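# Lutefisk-style output (DNMSO frozen dialect exemplar)
#Rank	Pr(c)	Quality	Sequence
>>> example.0
1	0.9000	0.7000	[100.0]AGK
2	0.5500	0.4100	PEPK
>>> example.1
1	0.6100	0.5900	S[MOD:00046]AMPLER
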