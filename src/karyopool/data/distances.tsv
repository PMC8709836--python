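# Printed pairwise cytogenetic distances (Nei standard D) between the ten
# quantitative-panel populations, lower triangle.
10
YAR-RY
NSK-BE	0.106
NSK-KA	0.081	0.002
NSK-SH	0.078	0.002	0.000
NSK-2R	0.096	0.000	0.001	0.001
NSK-LI	0.116	0.001	0.003	0.004	0.002
NSK-OR	0.069	0.007	0.003	0.003	0.006	0.007
NSK-YU	0.116	0.001	0.003	0.004	0.002	0.000	0.007
NSK-ST	0.080	0.002	0.000	0.000	0.001	0.003	0.002	0.003
KHA-EV	0.155	0.006	0.012	0.013	0.007	0.007	0.025	0.006	0.013
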