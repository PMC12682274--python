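individual_id,group_id,species,sex,age,habitat
A1,G1,chimpanzee,male,12,zoo
A2,G1,chimpanzee,female,25,zoo
A3,G1,chimpanzee,female,31,zoo
A4,G1,chimpanzee,male,8,zoo
A5,G1,chimpanzee,female,19,zoo
A6,G1,chimpanzee,male,40,zoo
B1,G2,bonobo,female,15,sanctuary
B2,G2,bonobo,male,22,sanctuary
B3,G2,bonobo,female,9,sanctuary
B4,G2,bonobo,female,27,sanctuary
B5,G2,bonobo,male,33,sanctuary
B6,G2,bonobo,female,11,sanctuary
B7,G2,bonobo,female,45,sanctuary
C1,G0,bonobo,male,14,zoo
C2,G0,bonobo,female,20,zoo
C3,G0,bonobo,female,26,zoo
C4,G0,bonobo,male,7,zoo
C5,G0,bonobo,female,38,zoo
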