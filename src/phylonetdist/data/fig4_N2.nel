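# Reconstruction (synthetic) of the separation-failure pair, second network:
# same equivalence-class multiset as its partner (so their d_e distance is 0)
# but the D-level edges cross over (D1 -> C2, D2 -> C1), destroying the
# directed triangles — the two networks are not isomorphic.
R	H
R	J
R	s
H	C1
H	D1
J	C2
J	D2
D1	C2
D1	V
D2	C1
D2	V
C1	M
C1	W
C2	M
C2	W
M	x
W	y
V	z
#label	s	s
#label	x	x
#label	y	y
#label	z	z
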