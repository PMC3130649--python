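child_label	parent_label
CT	Y
C	CT
DE	CT
D	DE
E	DE
F	CT
G	F
H	F
IJ	F
I	IJ
J	IJ
K	F
L	K
M	K
NO	K
N	NO
O1a	NO
O2	NO
O3	NO
P	K
Q	P
R	P
T	K
J2a10	J2a
J2a11	J2a
J2a13	J2a
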