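# Stage (1) of reducing the walkthrough network: every maximal pendant
# subtree replaced by a placeholder leaf labeled with its serialization.
R	A
R	B
A	C
A	D
B	E
B	tT
C	tP
C	H
D	3
D	G
E	tQ
E	F
F	6
F	H
H	G
G	tZ
#label	3	3
#label	6	6
#label	tP	(1,2)
#label	tQ	(4,5)
#label	tT	(10,9)
#label	tZ	(7,8)
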