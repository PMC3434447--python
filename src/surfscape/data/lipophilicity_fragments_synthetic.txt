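# SYNTHETIC lipophilic fragment table (Broto-style atomic contributions).
# These values are NOT the published Broto/Testa fragment constants; they
# are plausible per-atom-class stand-ins (aliphatic/aromatic carbons
# positive = hydrophobic; N/O negative = hydrophilic; S mildly positive)
# generated for testing and default operation. Replace this file with a
# table of published fragment values for production use; the loader
# accepts any file with the same three-column layout.
#
# residue  atom  fragment_value
# '*' residue rows are element-level fallbacks applied when no
# (residue, atom) entry matches.
ALA  N    -0.600
ALA  CA    0.450
ALA  C    -0.150
ALA  O    -0.400
ALA  OXT  -0.750
ALA  CB    0.450
ARG  N    -0.600
ARG  CA    0.450
ARG  C    -0.150
ARG  O    -0.400
ARG  OXT  -0.750
ARG  CB    0.450
ARG  CG    0.450
ARG  CD    0.450
ARG  NE   -0.850
ARG  CZ   -0.200
ARG  NH1  -0.850
ARG  NH2  -0.850
ASN  N    -0.600
ASN  CA    0.450
ASN  C    -0.150
ASN  O    -0.400
ASN  OXT  -0.750
ASN  CB    0.450
ASN  CG   -0.150
ASN  OD1  -0.400
ASN  ND2  -0.600
ASP  N    -0.600
ASP  CA    0.450
ASP  C    -0.150
ASP  O    -0.400
ASP  OXT  -0.750
ASP  CB    0.450
ASP  CG   -0.150
ASP  OD1  -0.750
ASP  OD2  -0.750
CYS  N    -0.600
CYS  CA    0.450
CYS  C    -0.150
CYS  O    -0.400
CYS  OXT  -0.750
CYS  CB    0.450
CYS  SG    0.450
GLN  N    -0.600
GLN  CA    0.450
GLN  C    -0.150
GLN  O    -0.400
GLN  OXT  -0.750
GLN  CB    0.450
GLN  CG    0.450
GLN  CD   -0.150
GLN  OE1  -0.400
GLN  NE2  -0.600
GLU  N    -0.600
GLU  CA    0.450
GLU  C    -0.150
GLU  O    -0.400
GLU  OXT  -0.750
GLU  CB    0.450
GLU  CG    0.450
GLU  CD   -0.150
GLU  OE1  -0.750
GLU  OE2  -0.750
GLY  N    -0.600
GLY  CA    0.450
GLY  C    -0.150
GLY  O    -0.400
GLY  OXT  -0.750
HIS  N    -0.600
HIS  CA    0.450
HIS  C    -0.150
HIS  O    -0.400
HIS  OXT  -0.750
HIS  CB    0.450
HIS  CG    0.330
HIS  ND1  -0.520
HIS  CD2   0.330
HIS  CE1   0.330
HIS  NE2  -0.520
ILE  N    -0.600
ILE  CA    0.450
ILE  C    -0.150
ILE  O    -0.400
ILE  OXT  -0.750
ILE  CB    0.450
ILE  CG1   0.450
ILE  CG2   0.450
ILE  CD1   0.450
LEU  N    -0.600
LEU  CA    0.450
LEU  C    -0.150
LEU  O    -0.400
LEU  OXT  -0.750
LEU  CB    0.450
LEU  CG    0.450
LEU  CD1   0.450
LEU  CD2   0.450
LYS  N    -0.600
LYS  CA    0.450
LYS  C    -0.150
LYS  O    -0.400
LYS  OXT  -0.750
LYS  CB    0.450
LYS  CG    0.450
LYS  CD    0.450
LYS  CE    0.450
LYS  NZ   -0.850
MET  N    -0.600
MET  CA    0.450
MET  C    -0.150
MET  O    -0.400
MET  OXT  -0.750
MET  CB    0.450
MET  CG    0.450
MET  SD    0.450
MET  CE    0.450
PHE  N    -0.600
PHE  CA    0.450
PHE  C    -0.150
PHE  O    -0.400
PHE  OXT  -0.750
PHE  CB    0.450
PHE  CG    0.330
PHE  CD1   0.330
PHE  CD2   0.330
PHE  CE1   0.330
PHE  CE2   0.330
PHE  CZ    0.330
PRO  N    -0.600
PRO  CA    0.450
PRO  C    -0.150
PRO  O    -0.400
PRO  OXT  -0.750
PRO  CB    0.450
PRO  CG    0.450
PRO  CD    0.450
SER  N    -0.600
SER  CA    0.450
SER  C    -0.150
SER  O    -0.400
SER  OXT  -0.750
SER  CB    0.450
SER  OG   -0.700
THR  N    -0.600
THR  CA    0.450
THR  C    -0.150
THR  O    -0.400
THR  OXT  -0.750
THR  CB    0.450
THR  OG1  -0.700
THR  CG2   0.450
TRP  N    -0.600
TRP  CA    0.450
TRP  C    -0.150
TRP  O    -0.400
TRP  OXT  -0.750
TRP  CB    0.450
TRP  CG    0.330
TRP  CD1   0.330
TRP  CD2   0.330
TRP  NE1  -0.520
TRP  CE2   0.330
TRP  CE3   0.330
TRP  CZ2   0.330
TRP  CZ3   0.330
TRP  CH2   0.330
TYR  N    -0.600
TYR  CA    0.450
TYR  C    -0.150
TYR  O    -0.400
TYR  OXT  -0.750
TYR  CB    0.450
TYR  CG    0.330
TYR  CD1   0.330
TYR  CD2   0.330
TYR  CE1   0.330
TYR  CE2   0.330
TYR  CZ    0.330
TYR  OH   -0.700
VAL  N    -0.600
VAL  CA    0.450
VAL  C    -0.150
VAL  O    -0.400
VAL  OXT  -0.750
VAL  CB    0.450
VAL  CG1   0.450
VAL  CG2   0.450
*    C     0.450
*    N    -0.600
*    O    -0.700
*    S     0.450
*    P    -0.500
*    H     0.100
*    X     0.000
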