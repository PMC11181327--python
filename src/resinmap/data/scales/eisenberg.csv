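# Eisenberg consensus hydrophobicity scale (normalized)
ALA,0.62
ARG,-2.53
ASN,-0.78
ASP,-0.90
CYS,0.29
GLN,-0.85
GLU,-0.74
GLY,0.48
HIS,-0.40
ILE,1.38
LEU,1.06
LYS,-1.50
MET,0.64
PHE,1.19
PRO,0.12
SER,-0.18
THR,-0.05
TRP,0.81
TYR,0.26
VAL,1.08
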