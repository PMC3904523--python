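# Pharmacophore class assignment for every heavy atom of the 20 standard amino acids.
# Eight classes: hydrophobic, positive, negative, hydrogen_acceptor, hydrogen_donor,
# aromatic, sulphur, neutral.
# Atoms that plausibly fit several classes receive a single label by the priority
# order sulphur > positive > negative > aromatic > hydrogen_donor > hydrogen_acceptor
# > hydrophobic > neutral (e.g. ring nitrogens of His/Trp are aromatic, hydroxyl
# oxygens are donors, proline backbone N has no amide hydrogen and is neutral).
# OXT marks the C-terminal carboxylate oxygen; it is excluded from the canonical
# per-residue inventory used for pharmacophore count vectors.
# columns: residue	atom	class
ALA	N	hydrogen_donor
ALA	CA	hydrophobic
ALA	C	neutral
ALA	O	hydrogen_acceptor
ALA	CB	hydrophobic
ALA	OXT	negative
ARG	N	hydrogen_donor
ARG	CA	hydrophobic
ARG	C	neutral
ARG	O	hydrogen_acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	hydrophobic
ARG	NE	positive
ARG	CZ	neutral
ARG	NH1	positive
ARG	NH2	positive
ARG	OXT	negative
ASN	N	hydrogen_donor
ASN	CA	hydrophobic
ASN	C	neutral
ASN	O	hydrogen_acceptor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	OD1	hydrogen_acceptor
ASN	ND2	hydrogen_donor
ASN	OXT	negative
ASP	N	hydrogen_donor
ASP	CA	hydrophobic
ASP	C	neutral
ASP	O	hydrogen_acceptor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	negative
ASP	OD2	negative
ASP	OXT	negative
CYS	N	hydrogen_donor
CYS	CA	hydrophobic
CYS	C	neutral
CYS	O	hydrogen_acceptor
CYS	CB	hydrophobic
CYS	SG	sulphur
CYS	OXT	negative
GLN	N	hydrogen_donor
GLN	CA	hydrophobic
GLN	C	neutral
GLN	O	hydrogen_acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	neutral
GLN	OE1	hydrogen_acceptor
GLN	NE2	hydrogen_donor
GLN	OXT	negative
GLU	N	hydrogen_donor
GLU	CA	hydrophobic
GLU	C	neutral
GLU	O	hydrogen_acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	neutral
GLU	OE1	negative
GLU	OE2	negative
GLU	OXT	negative
GLY	N	hydrogen_donor
GLY	CA	hydrophobic
GLY	C	neutral
GLY	O	hydrogen_acceptor
GLY	OXT	negative
HIS	N	hydrogen_donor
HIS	CA	hydrophobic
HIS	C	neutral
HIS	O	hydrogen_acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	aromatic
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	aromatic
HIS	OXT	negative
ILE	N	hydrogen_donor
ILE	CA	hydrophobic
ILE	C	neutral
ILE	O	hydrogen_acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
ILE	OXT	negative
LEU	N	hydrogen_donor
LEU	CA	hydrophobic
LEU	C	neutral
LEU	O	hydrogen_acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LEU	OXT	negative
LYS	N	hydrogen_donor
LYS	CA	hydrophobic
LYS	C	neutral
LYS	O	hydrogen_acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	hydrophobic
LYS	NZ	positive
LYS	OXT	negative
MET	N	hydrogen_donor
MET	CA	hydrophobic
MET	C	neutral
MET	O	hydrogen_acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	sulphur
MET	CE	hydrophobic
MET	OXT	negative
PHE	N	hydrogen_donor
PHE	CA	hydrophobic
PHE	C	neutral
PHE	O	hydrogen_acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic
PHE	CD1	aromatic
PHE	CD2	aromatic
PHE	CE1	aromatic
PHE	CE2	aromatic
PHE	CZ	aromatic
PHE	OXT	negative
PRO	N	neutral
PRO	CA	hydrophobic
PRO	C	neutral
PRO	O	hydrogen_acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	hydrophobic
PRO	OXT	negative
SER	N	hydrogen_donor
SER	CA	hydrophobic
SER	C	neutral
SER	O	hydrogen_acceptor
SER	CB	hydrophobic
SER	OG	hydrogen_donor
SER	OXT	negative
THR	N	hydrogen_donor
THR	CA	hydrophobic
THR	C	neutral
THR	O	hydrogen_acceptor
THR	CB	hydrophobic
THR	OG1	hydrogen_donor
THR	CG2	hydrophobic
THR	OXT	negative
TRP	N	hydrogen_donor
TRP	CA	hydrophobic
TRP	C	neutral
TRP	O	hydrogen_acceptor
TRP	CB	hydrophobic
TRP	CG	aromatic
TRP	CD1	aromatic
TRP	CD2	aromatic
TRP	NE1	aromatic
TRP	CE2	aromatic
TRP	CE3	aromatic
TRP	CZ2	aromatic
TRP	CZ3	aromatic
TRP	CH2	aromatic
TRP	OXT	negative
TYR	N	hydrogen_donor
TYR	CA	hydrophobic
TYR	C	neutral
TYR	O	hydrogen_acceptor
TYR	CB	hydrophobic
TYR	CG	aromatic
TYR	CD1	aromatic
TYR	CD2	aromatic
TYR	CE1	aromatic
TYR	CE2	aromatic
TYR	CZ	aromatic
TYR	OH	hydrogen_donor
TYR	OXT	negative
VAL	N	hydrogen_donor
VAL	CA	hydrophobic
VAL	C	neutral
VAL	O	hydrogen_acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
VAL	OXT	negative
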