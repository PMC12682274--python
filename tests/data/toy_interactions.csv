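group_id,actor_id,receiver_id,weight
G1,A1,A2,1
G1,A1,A3,2
G1,A1,A4,3
G1,A1,A5,4
G1,A1,A6,5
G1,A2,A1,2
G1,A2,A3,3
G1,A2,A4,4
G1,A2,A5,5
G1,A2,A6,6
G1,A3,A1,5
G1,A3,A2,4
G1,A3,A4,3
G1,A3,A5,2
G1,A3,A6,1
G1,A4,A1,1
G1,A4,A2,1
G1,A4,A3,2
G1,A4,A5,3
G1,A4,A6,8
G1,A5,A1,2
G1,A5,A2,2
G1,A5,A3,4
G1,A6,A1,2
G1,A6,A2,2
G1,A6,A3,2
G1,A6,A4,2
G1,A6,A5,2
G2,B1,B2,1
G2,B1,B3,2
G2,B1,B4,3
G2,B1,B5,4
G2,B1,B6,5
G2,B1,B7,6
G2,B2,B1,3
G2,B2,B3,1
G2,B2,B4,4
G2,B2,B5,1
G2,B2,B6,5
G2,B3,B1,2
G2,B3,B2,7
G2,B3,B4,1
G2,B3,B5,8
G2,B3,B7,2
G2,B4,B1,1
G2,B4,B2,2
G2,B4,B3,2
G2,B4,B5,3
G2,B4,B6,9
G2,B5,B1,4
G2,B5,B2,4
G2,B5,B3,4
G2,B5,B4,4
G2,B5,B6,1
G2,B5,B7,1
G2,B6,B1,5
G2,B6,B7,5
G0,C1,C2,3
G0,C2,C3,2
G0,C3,C1,1
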