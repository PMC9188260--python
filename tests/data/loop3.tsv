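id	equation	lb	ub	reversible	exchange
EX_in	M1 ->	-10.0	0.0	0	1
C1	M1 -> M2	-1000.0	1000.0	1	0
C2	M2 -> M3	-1000.0	1000.0	1	0
C3	M3 -> M1	-1000.0	1000.0	1	0
EX_out	M3 ->	0.0	1000.0	0	1
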