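population	arm	sequence	frequency
YAR-RY	A	p'agiA1	1
YAR-RY	A	p'agiA2	0
YAR-RY	B	p'agiB1	1
YAR-RY	B	p'agiB2	0
YAR-RY	B	p'agiB3	0
YAR-RY	C	h'agiC1	1
YAR-RY	C	p'agiC2	0
YAR-RY	D	p'agiD1	1
YAR-RY	D	p'agiD2	0
YAR-RY	D	p'agiD3	0
YAR-RY	E	h'agiE1	1
YAR-RY	E	p'agiE2	0
YAR-RY	F	p'agiF1	1
YAR-RY	F	p'agiF2	0
YAR-RY	F	p'agiF3	0
YAR-RY	G	p'agiG1	1
NSK-BE	A	p'agiA1	1
NSK-BE	A	p'agiA2	0
NSK-BE	B	p'agiB1	0.178
NSK-BE	B	p'agiB2	0.822
NSK-BE	B	p'agiB3	0
NSK-BE	C	h'agiC1	1
NSK-BE	C	p'agiC2	0
NSK-BE	D	p'agiD1	1
NSK-BE	D	p'agiD2	0
NSK-BE	D	p'agiD3	0
NSK-BE	E	h'agiE1	1
NSK-BE	E	p'agiE2	0
NSK-BE	F	p'agiF1	0.900
NSK-BE	F	p'agiF2	0.100
NSK-BE	F	p'agiF3	0
NSK-BE	G	p'agiG1	1
NSK-KA	A	p'agiA1	1
NSK-KA	A	p'agiA2	0
NSK-KA	B	p'agiB1	0.279
NSK-KA	B	p'agiB2	0.721
NSK-KA	B	p'agiB3	0
NSK-KA	C	h'agiC1	1
NSK-KA	C	p'agiC2	0
NSK-KA	D	p'agiD1	1
NSK-KA	D	p'agiD2	0
NSK-KA	D	p'agiD3	0
NSK-KA	E	h'agiE1	1
NSK-KA	E	p'agiE2	0
NSK-KA	F	p'agiF1	0.912
NSK-KA	F	p'agiF2	0.088
NSK-KA	F	p'agiF3	0
NSK-KA	G	p'agiG1	1
NSK-SH	A	p'agiA1	1
NSK-SH	A	p'agiA2	0
NSK-SH	B	p'agiB1	0.291
NSK-SH	B	p'agiB2	0.707
NSK-SH	B	p'agiB3	0.002
NSK-SH	C	h'agiC1	1
NSK-SH	C	p'agiC2	0
NSK-SH	D	p'agiD1	0.998
NSK-SH	D	p'agiD2	0
NSK-SH	D	p'agiD3	0.002
NSK-SH	E	h'agiE1	0.996
NSK-SH	E	p'agiE2	0.004
NSK-SH	F	p'agiF1	0.911
NSK-SH	F	p'agiF2	0.087
NSK-SH	F	p'agiF3	0.002
NSK-SH	G	p'agiG1	1
NSK-2R	A	p'agiA1	1
NSK-2R	A	p'agiA2	0
NSK-2R	B	p'agiB1	0.214
NSK-2R	B	p'agiB2	0.786
NSK-2R	B	p'agiB3	0
NSK-2R	C	h'agiC1	1
NSK-2R	C	p'agiC2	0
NSK-2R	D	p'agiD1	1
NSK-2R	D	p'agiD2	0
NSK-2R	D	p'agiD3	0
NSK-2R	E	h'agiE1	1
NSK-2R	E	p'agiE2	0
NSK-2R	F	p'agiF1	0.929
NSK-2R	F	p'agiF2	0.071
NSK-2R	F	p'agiF3	0
NSK-2R	G	p'agiG1	1
NSK-LI	A	p'agiA1	1
NSK-LI	A	p'agiA2	0
NSK-LI	B	p'agiB1	0.359
NSK-LI	B	p'agiB2	0.641
NSK-LI	B	p'agiB3	0
NSK-LI	C	h'agiC1	1
NSK-LI	C	p'agiC2	0
NSK-LI	D	p'agiD1	1
NSK-LI	D	p'agiD2	0
NSK-LI	D	p'agiD3	0
NSK-LI	E	h'agiE1	1
NSK-LI	E	p'agiE2	0
NSK-LI	F	p'agiF1	0.797
NSK-LI	F	p'agiF2	0.203
NSK-LI	F	p'agiF3	0
NSK-LI	G	p'agiG1	1
NSK-OR	A	p'agiA1	1
NSK-OR	A	p'agiA2	0
NSK-OR	B	p'agiB1	0.154
NSK-OR	B	p'agiB2	0.846
NSK-OR	B	p'agiB3	0
NSK-OR	C	h'agiC1	1
NSK-OR	C	p'agiC2	0
NSK-OR	D	p'agiD1	1
NSK-OR	D	p'agiD2	0
NSK-OR	D	p'agiD3	0
NSK-OR	E	h'agiE1	1
NSK-OR	E	p'agiE2	0
NSK-OR	F	p'agiF1	0.837
NSK-OR	F	p'agiF2	0.163
NSK-OR	F	p'agiF3	0
NSK-OR	G	p'agiG1	1
NSK-YU	A	p'agiA1	1
NSK-YU	A	p'agiA2	0
NSK-YU	B	p'agiB1	0.152
NSK-YU	B	p'agiB2	0.848
NSK-YU	B	p'agiB3	0
NSK-YU	C	h'agiC1	1
NSK-YU	C	p'agiC2	0
NSK-YU	D	p'agiD1	1
NSK-YU	D	p'agiD2	0
NSK-YU	D	p'agiD3	0
NSK-YU	E	h'agiE1	1
NSK-YU	E	p'agiE2	0
NSK-YU	F	p'agiF1	0.851
NSK-YU	F	p'agiF2	0.149
NSK-YU	F	p'agiF3	0
NSK-YU	G	p'agiG1	1
NSK-ST	A	p'agiA1	1
NSK-ST	A	p'agiA2	0
NSK-ST	B	p'agiB1	0.288
NSK-ST	B	p'agiB2	0.712
NSK-ST	B	p'agiB3	0
NSK-ST	C	h'agiC1	1
NSK-ST	C	p'agiC2	0
NSK-ST	D	p'agiD1	0.991
NSK-ST	D	p'agiD2	0
NSK-ST	D	p'agiD3	0.009
NSK-ST	E	h'agiE1	1
NSK-ST	E	p'agiE2	0
NSK-ST	F	p'agiF1	0.889
NSK-ST	F	p'agiF2	0.111
NSK-ST	F	p'agiF3	0
NSK-ST	G	p'agiG1	1
KHA-EV	A	p'agiA1	1
KHA-EV	A	p'agiA2	0
KHA-EV	B	p'agiB1	0
KHA-EV	B	p'agiB2	1
KHA-EV	B	p'agiB3	0
KHA-EV	C	h'agiC1	1
KHA-EV	C	p'agiC2	0
KHA-EV	D	p'agiD1	0.986
KHA-EV	D	p'agiD2	0.014
KHA-EV	D	p'agiD3	0
KHA-EV	E	h'agiE1	1
KHA-EV	E	p'agiE2	0
KHA-EV	F	p'agiF1	1
KHA-EV	F	p'agiF2	0
KHA-EV	F	p'agiF3	0
KHA-EV	G	p'agiG1	1
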