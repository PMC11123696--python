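db	compound	formula	mw	clogp	tpsa	hba	hbd	gold_chemplp	dockthor
MEGx	NP-016468	C25H26O6	422.47	6.23	107.22	6	4	89.99	-10.924
MEGx	NP-025047	C32H36O6	516.63	6.67	71.06	4	0	94.67	-12.169
MEGx	NP-025357	C30H32O9	536.57	3.77	123.91	8	3	101.02	-11.800
MEGx	NP-025358	C31H34O9	550.60	3.91	112.91	8	2	99.42	-11.984
NATx	NAT28-412055	C27H34N4O	430.59	4.66	63.84	4	1	99.19	-11.061
NATx	NAT28-416626	C26H29FN4O2	448.54	3.72	80.91	4	1	101.31	-11.352
NATx	NAT14-350419	C33H41N5O3	555.72	4.03	90.71	4	2	99.97	-11.554
NATx	NAT13-340161	C28H29FN4O3	488.56	4.62	84.42	6	1	99.96	-11.028
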