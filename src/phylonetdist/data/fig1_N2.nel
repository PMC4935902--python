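# Reconstruction (synthetic) of the second refinement network on
# {1,2,3,4,x}: identical semiequivalence structure to its partner, but the
# reticulation parents are wired across the root split (h1 under c and e,
# h2 under d and f), so the pair is not isomorphic to it.
r	a
r	b
a	c
a	d
b	e
b	f
c	1
c	h1
d	2
d	h2
e	3
e	h1
f	4
f	h2
h1	g
h2	g
g	x
#label	1	1
#label	2	2
#label	3	3
#label	4	4
#label	x	x
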