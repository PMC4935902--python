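# Stage (2) of reducing the walkthrough network: the convergent set {H, G}
# processed — H deleted, its parents C and F rewired onto G (the surviving
# parent of the affected placeholder leaf); no unary node arises.
R	A
R	B
A	C
A	D
B	E
B	tT
C	tP
C	G
D	3
D	G
E	tQ
E	F
F	6
F	G
G	tZ
#label	3	3
#label	6	6
#label	tP	(1,2)
#label	tQ	(4,5)
#label	tT	(10,9)
#label	tZ	(7,8)
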