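resname	one_letter	polarity_class
ALA	A	apolar
CYS	C	apolar
GLU	E	charged
ASP	D	charged
GLY	G	apolar
PHE	F	apolar
ILE	I	apolar
HIS	H	charged
LYS	K	charged
LEU	L	apolar
MET	M	apolar
ASN	N	polar
GLN	Q	polar
PRO	P	apolar
ARG	R	charged
SER	S	polar
THR	T	polar
VAL	V	apolar
TRP	W	polar
TYR	Y	polar
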