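# Simple nucleotide scoring: match +5, mismatch -4 (EDNAFULL-style core).
   A  C  G  T
A  5 -4 -4 -4
C -4  5 -4 -4
G -4 -4  5 -4
T -4 -4 -4  5
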