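# Ancestral Crucifer Karyotype (n = 8): chromosome, upper-arm blocks, lower-arm blocks.
# Blocks are listed head->tail in ancestral reading; the centromere sits
# between the two arms.  Override with your own table to change arm splits
# (e.g. AK7 as S | T,U instead of the packaged S,T | U).
AK1	A,B	C
AK2	D	E
AK3	F	G,H
AK4	I	J
AK5	K-L	M-N
AK6	O,P	Q,R
AK7	S,T	U
AK8	V	W,X
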