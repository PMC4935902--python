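# Reconstruction (synthetic) of the first of the two motivating refinement
# networks on taxa {1,2,3,4,x}: two reticulate nodes H1, H2 feed a shared
# reticulate node G above the hybrid taxon x.  H1's parents C, D sit under A;
# H2's parents E, F sit under B.
R	A
R	B
A	C
A	D
B	E
B	F
C	1
C	H1
D	2
D	H1
E	3
E	H2
F	4
F	H2
H1	G
H2	G
G	x
#label	1	1
#label	2	2
#label	3	3
#label	4	4
#label	x	x
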