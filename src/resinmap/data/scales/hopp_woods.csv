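# Hopp-Woods hydrophilicity scale (dimensionless)
ALA,-0.5
ARG,3.0
ASN,0.2
ASP,3.0
CYS,-1.0
GLN,0.2
GLU,3.0
GLY,0.0
HIS,-0.5
ILE,-1.8
LEU,-1.8
LYS,3.0
MET,-1.3
PHE,-2.5
PRO,0.0
SER,0.3
THR,-0.4
TRP,-3.4
TYR,-2.3
VAL,-1.5
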