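# Stage (3): pendant subtrees re-expanded — the reduced version of the
# walkthrough network.
R	A
R	B
A	C
A	D
B	E
B	T
C	P
C	G
D	3
D	G
E	Q
E	F
F	6
F	G
G	Z
P	1
P	2
Q	4
Q	5
Z	7
Z	8
T	9
T	10
#label	1	1
#label	2	2
#label	3	3
#label	4	4
#label	5	5
#label	6	6
#label	7	7
#label	8	8
#label	9	9
#label	10	10
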