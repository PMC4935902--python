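# The common reduced version of the two refinement networks on {1,2,3,4,x}:
# both reticulations deleted, their four former parents rewired onto G.
R	A
R	B
A	C
A	D
B	E
B	F
C	1
C	G
D	2
D	G
E	3
E	G
F	4
F	G
G	x
#label	1	1
#label	2	2
#label	3	3
#label	4	4
#label	x	x
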