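>EXOpcr-69-bio mod5=biotin mod3=none
CCAGGGAGTGATGGTTGGAATGAACCCGCTTCAGCAAGACTCACTCTGAAGTATCCGATA
GAACACGGC
>EXO-F mod5=none mod3=none
CCAGGGAGTGATGGTTGGAATG
>EXO-R mod5=none mod3=none
GCCGTGTTGGCTCGGATAC
>Probe-Rox mod5=rox mod3=none
AGTGAGTCTTGCTGAAGCGG
>Proximity_C1 mod5=none mod3=none
CGCATCGCCCTTGGACTACGACTGACGAACCGCTTTGCCTGACTGATCGCTAAATCGTG
>Proximity_C2 mod5=phosphate mod3=none
TCGTGTCTAAAGTCCGTTACCTTGATTCCCCTAACCCTCTTGAAAAATTCGG
>Bio-proximity_C2 mod5=none mod3=biotin
TCGTGTCTAAAGTCCGTTACCTTGATTCCCCTAACCCTCTTGAAAAATTCGG
>Bio-proximity_C1 mod5=biotin mod3=none
GAACCGCTTTGCCTGACTGATCGCTAAATCGTG
>Proximity_cnct mod5=none mod3=none
TACTTAGACACGACACGATTTAGTTT
>Proximity_F mod5=none mod3=none
CATCGCCCTTGGACTACGA
>Proximity_R mod5=none mod3=none
GGGAATCAAGGTAACGGACTTTAG
>TaqMan_SLC mod5=fam mod3=mgb
TGACGAACCGCTTTGCCTGA
>C1C2 mod5=none mod3=none
CGCATCGCCCTTGGACTACGACTGACGAACCGCTTTGCCTGACTGATCGCTAAATCGTGT
CGTGTCTAAAGTCCGTTACCTTGATTCCCCTAACCCTCTTGAAAAATTCGG
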