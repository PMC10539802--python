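residue_type,mean_ppm,sd_ppm
ALA,8.194,0.577
ARG,8.234,0.612
ASN,8.324,0.625
ASP,8.299,0.588
CYS,8.387,0.665
GLN,8.216,0.599
GLU,8.330,0.608
GLY,8.327,0.770
HIS,8.250,0.684
ILE,8.262,0.694
LEU,8.217,0.735
LYS,8.177,0.603
MET,8.256,0.593
PHE,8.363,0.724
SER,8.286,0.594
THR,8.235,0.617
TRP,8.276,0.782
TYR,8.320,0.721
VAL,8.271,0.687
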