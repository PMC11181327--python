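# Aromaphilicity index -- SYNTHETIC stand-in scale.
# Quantifies residue affinity for aromatic probes. The published residue-level
# index was not available when this package was assembled, so these values are
# a synthetic surrogate preserving the qualitative ordering the index is used
# for: aromatics (TRP > TYR > PHE > HIS) highest, ARG above LYS (cation-pi
# capable guanidinium), aliphatics intermediate, charged/polar lowest.
# Replace with the published scale via a user CSV for production analyses.
ALA,0.30
ARG,0.85
ASN,0.25
ASP,0.10
CYS,0.55
GLN,0.30
GLU,0.10
GLY,0.20
HIS,1.10
ILE,0.50
LEU,0.50
LYS,0.30
MET,0.70
PHE,1.40
PRO,0.45
SER,0.20
THR,0.25
TRP,1.80
TYR,1.50
VAL,0.45
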