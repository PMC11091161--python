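# Coarse-grained (CG) typing rules: one primitive site per chemical group.
#
# Same format as fa_rules.txt.  Atoms without a covering rule are
# intentionally omitted from the primitive cloud (backbone N and O, and
# side-chain amide O/N, which are represented by their AmideC carbon;
# ring atoms are represented by their Aro centroid).
@types AmideC,OH,Pos,Neg,Aro,Ali,S
@cterm O,OXT Neg group
* C AmideC atom
* CA Ali atom
ALA CB Ali atom
ARG CB,CG,CD Ali atom
ARG CZ,NE,NH1,NH2 Pos group
ASN CB Ali atom
ASN CG AmideC atom
ASP CB,CG Ali atom
ASP OD1,OD2 Neg group
CYS CB Ali atom
CYS SG S atom
GLN CB,CG Ali atom
GLN CD AmideC atom
GLU CB,CG,CD Ali atom
GLU OE1,OE2 Neg group
HIS CB Ali atom
HIS CG,ND1,CD2,CE1,NE2 Aro group
ILE CB,CG1,CG2,CD1 Ali atom
LEU CB,CG,CD1,CD2 Ali atom
LYS CB,CG,CD,CE Ali atom
LYS NZ Pos atom
MET CB,CG,CE Ali atom
MET SD S atom
PHE CB Ali atom
PHE CG,CD1,CD2,CE1,CE2,CZ Aro group
PRO CB,CG,CD Ali atom
SER CB Ali atom
SER OG OH atom
THR CB,CG2 Ali atom
THR OG1 OH atom
TRP CB Ali atom
TRP CG,CD1,CD2,NE1,CE2 Aro group
TRP CD2,CE2,CE3,CZ2,CZ3,CH2 Aro group
TYR CB Ali atom
TYR CG,CD1,CD2,CE1,CE2,CZ Aro group
TYR OH OH atom
VAL CB,CG1,CG2 Ali atom
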