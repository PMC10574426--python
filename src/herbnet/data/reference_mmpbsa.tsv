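complex	vdw	cou	pb	sa	minus_t_delta_s	mm	delta_h	delta_g
XT	-42.13	-3.20	14.48	-4.53	5.35	-45.34	-35.38	-30.03
AT	-35.42	-5.74	21.43	-5.42	1.73	-41.16	-25.15	-23.42
IM	-35.99	-9.88	35.93	-5.71	3.69	-45.88	-15.65	-11.96
LM	-32.95	-10.11	33.36	-5.03	3.74	-43.06	-14.73	-10.99
FM	-38.02	-5.47	23.80	-5.20	2.89	-43.49	-24.89	-22.00
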