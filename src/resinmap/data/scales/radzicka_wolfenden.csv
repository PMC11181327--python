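# Radzicka-Wolfenden hydrophobicity (water-to-cyclohexane transfer, kcal/mol)
# PRO has no measured side-chain value in the original transfer data; set to
# 0.0 by convention so the 20-residue completeness contract holds.
ALA,1.81
ARG,-14.92
ASN,-6.64
ASP,-8.72
CYS,1.28
GLN,-5.54
GLU,-6.81
GLY,0.94
HIS,-4.66
ILE,4.92
LEU,4.92
LYS,-5.55
MET,2.35
PHE,2.98
PRO,0.0
SER,-3.40
THR,-2.57
TRP,2.33
TYR,-0.14
VAL,4.04
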