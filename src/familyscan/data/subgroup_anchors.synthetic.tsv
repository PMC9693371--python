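id	subgroup
C1_anchor1	C1
C1_anchor2	C1
C2_anchor1	C2
C2_anchor2	C2
C5_anchor1	C5
C5_anchor2	C5
C7_anchor1	C7
C7_anchor2	C7
C17_anchor1	C17
C17_anchor2	C17
C20_anchor1	C20
C20_anchor2	C20
C22_anchor1	C22
C22_anchor2	C22
C27_anchor1	C27
C27_anchor2	C27
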