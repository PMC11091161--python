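# Full-atom (FA) typing rules: one primitive atom per heavy atom.
#
# Format: <residue|*> <atom[,atom...]> <ptype> <atom|group>
#   *       applies to every canonical residue (backbone atoms)
#   atom    one primitive per listed atom, at the atom position
#   group   one primitive at the geometric center of the listed atoms
# Directives:
#   @types  ordered primitive type set of the scheme
#   @strict every heavy atom must be covered by some rule
#   @cterm  applied instead of the normal rules for these atoms when the
#           residue carries an OXT (terminal carboxylate is charged)
#
# Protonation defaults: Arg/Lys positive, Asp/Glu negative, His neutral
# (and treated as aromatic); carbonyl/carboxyl/amide carbons are C_ali
# since the scheme has no carbonyl-carbon type.
@types O_neg,O_neu,N_pos,N_neu,C_ali,C_aro,S
@strict
@cterm O,OXT O_neg atom
* N N_neu atom
* CA C_ali atom
* C C_ali atom
* O O_neu atom
* OXT O_neg atom
ALA CB C_ali atom
ARG CB,CG,CD,CZ C_ali atom
ARG NE,NH1,NH2 N_pos atom
ASN CB,CG C_ali atom
ASN OD1 O_neu atom
ASN ND2 N_neu atom
ASP CB,CG C_ali atom
ASP OD1,OD2 O_neg atom
CYS CB C_ali atom
CYS SG S atom
GLN CB,CG,CD C_ali atom
GLN OE1 O_neu atom
GLN NE2 N_neu atom
GLU CB,CG,CD C_ali atom
GLU OE1,OE2 O_neg atom
HIS CB C_ali atom
HIS CG,CD2,CE1 C_aro atom
HIS ND1,NE2 N_neu atom
ILE CB,CG1,CG2,CD1 C_ali atom
LEU CB,CG,CD1,CD2 C_ali atom
LYS CB,CG,CD,CE C_ali atom
LYS NZ N_pos atom
MET CB,CG,CE C_ali atom
MET SD S atom
PHE CB C_ali atom
PHE CG,CD1,CD2,CE1,CE2,CZ C_aro atom
PRO CB,CG,CD C_ali atom
SER CB C_ali atom
SER OG O_neu atom
THR CB,CG2 C_ali atom
THR OG1 O_neu atom
TRP CB C_ali atom
TRP CG,CD1,CD2,CE2,CE3,CZ2,CZ3,CH2 C_aro atom
TRP NE1 N_neu atom
TYR CB C_ali atom
TYR CG,CD1,CD2,CE1,CE2,CZ C_aro atom
TYR OH O_neu atom
VAL CB,CG1,CG2 C_ali atom
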