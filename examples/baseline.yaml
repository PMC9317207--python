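# Reference parameter set (bistable regime): both the no-service corner
# O(0,0) and the bilateral-cooperation corner C(1,1) are stable.
U1: 1.0
U2: 1.2
P1: 2.23
P2: 3.0
R1: 2.2
R2: 2.42
C1: 4.0
C2: 4.21
S1: 1.4
S2: 1.6
S1p: 1.59
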