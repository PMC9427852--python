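MEME version 4

ALPHABET= ACGU

strands: +

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 U 0.25000

MOTIF DEMO_CPEB2 CPEB2
letter-probability matrix: alphabet= ACGU w= 6 nsites= 20 E= 0
 0.026667 0.026667 0.026667 0.920000
 0.026667 0.026667 0.026667 0.920000
 0.026667 0.026667 0.026667 0.920000
 0.026667 0.026667 0.026667 0.920000
 0.920000 0.026667 0.026667 0.026667
 0.026667 0.026667 0.026667 0.920000

MOTIF DEMO_CPEB4 CPEB4
letter-probability matrix: alphabet= ACGU w= 7 nsites= 20 E= 0
 0.033333 0.033333 0.033333 0.900000
 0.033333 0.033333 0.033333 0.900000
 0.033333 0.033333 0.033333 0.900000
 0.033333 0.033333 0.033333 0.900000
 0.900000 0.033333 0.033333 0.033333
 0.900000 0.033333 0.033333 0.033333
 0.033333 0.033333 0.033333 0.900000

MOTIF DEMO_PCBP1 PCBP1
letter-probability matrix: alphabet= ACGU w= 7 nsites= 20 E= 0
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.040000 0.880000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000

MOTIF DEMO_FXR1 FXR1
letter-probability matrix: alphabet= ACGU w= 6 nsites= 20 E= 0
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.880000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000

MOTIF DEMO_DDX3X DDX3X
letter-probability matrix: alphabet= ACGU w= 6 nsites= 20 E= 0
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.040000 0.040000 0.880000 0.040000
 0.880000 0.040000 0.040000 0.040000

MOTIF DEMO_ARE ELAVL1
letter-probability matrix: alphabet= ACGU w= 5 nsites= 20 E= 0
 0.920000 0.026667 0.026667 0.026667
 0.026667 0.026667 0.026667 0.920000
 0.026667 0.026667 0.026667 0.920000
 0.026667 0.026667 0.026667 0.920000
 0.920000 0.026667 0.026667 0.026667

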