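# Reconstruction (synthetic) of the separation-failure pair, first network:
# {H, J} is the only superconvergent set (shared parent set {R}); the
# equivalent-but-distinct cascades D1/D2 and C1/C2 merge into the reticulate
# nodes M, W, V.  Here each of H's two downward paths closes a directed
# triangle (H -> C1 and H -> D1 -> C1).
R	H
R	J
R	s
H	C1
H	D1
J	C2
J	D2
D1	C1
D1	V
D2	C2
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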