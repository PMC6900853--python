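>spt10_like synthetic Spt10-style histone-UAS look-alike
A [ 1 57 1 1 1 1 57 57 1 1 1 1 ]
C [ 1 1 1 1 57 57 1 1 57 1 1 1 ]
G [ 57 1 1 1 1 1 1 1 1 57 57 1 ]
T [ 1 1 57 57 1 1 1 1 1 1 1 57 ]
>hap_like synthetic HAP/NF-Y-style CCAAT-box look-alike
A [ 57 1 1 1 57 1 1 57 57 1 1 1 1 1 57 ]
C [ 1 1 1 1 1 57 57 1 1 1 57 1 1 57 1 ]
G [ 1 57 1 57 1 1 1 1 1 1 1 57 1 1 1 ]
T [ 1 1 57 1 1 1 1 1 1 57 1 1 57 1 1 ]
>crea_like synthetic CreA/MIG1-style look-alike
A [ 1 1 1 1 57 1 1 1 ]
C [ 1 57 1 1 1 1 1 57 ]
G [ 57 1 57 57 1 57 1 1 ]
T [ 1 1 1 1 1 1 57 1 ]
>neg_like synthetic NEG-element look-alike
A [ 1 57 1 1 1 1 1 1 1 57 ]
C [ 57 1 1 1 1 1 1 57 1 1 ]
G [ 1 1 1 1 57 57 57 1 57 1 ]
T [ 1 1 57 57 1 1 1 1 1 1 ]
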