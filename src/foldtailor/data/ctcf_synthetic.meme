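MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF ctcf_synthetic
letter-probability matrix: alength= 4 w= 19 nsites= 100 E= 0
 0.10 0.20 0.10 0.60
 0.05 0.05 0.85 0.05
 0.03 0.03 0.91 0.03
 0.03 0.91 0.03 0.03
 0.04 0.58 0.04 0.34
 0.70 0.10 0.10 0.10
 0.05 0.75 0.15 0.05
 0.03 0.91 0.03 0.03
 0.60 0.04 0.32 0.04
 0.03 0.03 0.91 0.03
 0.05 0.05 0.85 0.05
 0.10 0.05 0.75 0.10
 0.04 0.04 0.88 0.04
 0.06 0.10 0.78 0.06
 0.10 0.70 0.10 0.10
 0.15 0.10 0.65 0.10
 0.15 0.55 0.15 0.15
 0.20 0.15 0.15 0.50
 0.40 0.20 0.25 0.15
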