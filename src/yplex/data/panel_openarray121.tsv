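marker	haplogroup	ancestral	derived	variant_class	dye_ancestral	dye_derived	call_rate_or_failed	redundancy_group
M216	C	C	T	substitution	VIC	FAM	95.8	.
M168	CT	C	T	substitution	VIC	FAM	98.1	.
M174	D	T	C	substitution	VIC	FAM	97.7	.
M145	DE	G	A	substitution	VIC	FAM	96.6	DE_ctrl
M203	DE	G	C	substitution	VIC	FAM	96.6	DE_ctrl
M96	E	G	C	substitution	VIC	FAM	98.1	.
P147	E1	T	A	substitution	VIC	FAM	97.7	.
M33	E1a	A	C	substitution	VIC	FAM	95.5	.
P177	E1b	C	T	substitution	VIC	FAM	93.6	.
P2	E1b1	C	T	substitution	VIC	FAM	97.3	.
M2	E1b1a	A	G	substitution	VIC	FAM	97.0	.
M215	E1b1b	A	G	substitution	VIC	FAM	97.3	.
M35	E1b1b1	G	C	substitution	VIC	FAM	95.8	.
M78	E1b1b1a	C	T	substitution	VIC	FAM	98.1	.
V12	E1b1b1a1	A	G	substitution	VIC	FAM	97.3	.
V13	E1b1b1a2	G	A	substitution	VIC	FAM	97.0	.
V22	E1b1b1a3	T	C	substitution	VIC	FAM	97.7	.
V65	E1b1b1a4	G	T	substitution	VIC	FAM	96.2	.
M81	E1b1b1b	C	T	substitution	VIC	FAM	89.8	.
M123	E1b1b1c	G	A	substitution	VIC	FAM	97.7	.
M281	E1b1b1d	G	A	substitution	VIC	FAM	97.0	.
V6	E1b1b1e	G	C	substitution	VIC	FAM	99.6	.
P72	E1b1b1f	G	A	substitution	VIC	FAM	98.1	.
M329	E1b1c	G	C	substitution	VIC	FAM	98.1	.
P75	E1b2	G	A	substitution	VIC	FAM	Failed	.
M75	E2	G	A	substitution	VIC	FAM	97.7	.
M89	F	C	T	substitution	VIC	FAM	97.7	.
M201	G	G	T	substitution	VIC	FAM	95.5	.
M285	G1	G	C	substitution	VIC	FAM	96.6	.
P20	G1a	C	del	deletion	VIC	FAM	95.8	.
P76	G1b	G	C	substitution	VIC	FAM	98.9	.
P287	G2	G	T	substitution	VIC	FAM	96.6	.
P15	G2a	C	T	substitution	VIC	FAM	97.7	.
M287	G2b	A	T	substitution	VIC	FAM	97.0	.
M377	G2c	A	G	substitution	VIC	FAM	94.7	.
M69	H	T	C	substitution	VIC	FAM	97.0	.
M52	H1	A	C	substitution	VIC	FAM	95.5	.
Apt	H2	G	A	substitution	VIC	FAM	92.8	.
M170	I	A	C	substitution	VIC	FAM	97.0	.
M253	I1	C	T	substitution	VIC	FAM	97.0	.
M21	I1a	A	T	substitution	VIC	FAM	96.2	.
M72	I1b1	A	G	substitution	VIC	FAM	98.1	.
P109	I1c	G	A	substitution	VIC	FAM	95.8	.
P259	I1d	T	G	substitution	VIC	FAM	96.6	.
P215	I2	A	G	substitution	VIC	FAM	95.1	.
P37.2	I2a	T	C	substitution	VIC	FAM	96.6	.
P41.2	I2a1	T	C	substitution	VIC	FAM	97.3	.
M26	I2a2	G	A	substitution	VIC	FAM	95.5	.
M223	I2b	C	T	substitution	VIC	FAM	96.2	.
M284	I2b1	ACAA	del	deletion	VIC	FAM	96.2	.
M379	I2b2	GT	del	deletion	VIC	FAM	97.0	.
P95	I2b4	G	T	substitution	VIC	FAM	95.1	.
P123	IJ	T	C	substitution	VIC	FAM	94.3	.
M304	J	A	C	substitution	VIC	FAM	94.3	.
M267	J1	T	G	substitution	VIC	FAM	95.5	.
M62	J1a	T	C	substitution	VIC	FAM	95.5	.
M365	J1b	A	G	substitution	VIC	FAM	Failed	.
M390	J1c	A	ins	insertion	VIC	FAM	Failed	.
P56	J1d	A	G	substitution	VIC	FAM	96.6	.
P58	J1e	T	C	substitution	VIC	FAM	95.5	.
M172	J2	T	G	substitution	VIC	FAM	96.6	.
M410	J2a	A	G	substitution	VIC	FAM	95.5	.
M47	J2a1	G	A	substitution	VIC	FAM	96.6	.
M340	J2a10	G	C	substitution	VIC	FAM	94.7	.
M419	J2a11	AAAAG	del	deletion	VIC	FAM	95.8	.
P81	J2a12	C	T	substitution	VIC	FAM	Failed	.
P279	J2a13	G	A	substitution	VIC	FAM	98.1	.
M67	J2a2	A	T	substitution	VIC	FAM	95.1	.
M92	J2a2a	T	C	substitution	VIC	FAM	96.2	.
M68	J2a3	A	G	substitution	VIC	FAM	91.3	.
M137	J2a4	T	C	substitution	VIC	FAM	97.7	.
M158	J2a5	G	A	substitution	VIC	FAM	97.7	.
M289	J2a6	G	A	substitution	VIC	FAM	96.6	.
M318	J2a7	T	C	substitution	VIC	FAM	97.3	.
M319	J2a8	T	A	substitution	VIC	FAM	97.7	.
M339	J2a9	T	G	substitution	VIC	FAM	97.7	.
M12	J2b	G	T	substitution	VIC	FAM	97.0	.
M205	J2b1	T	A	substitution	VIC	FAM	98.1	.
M241	J2b2	G	A	substitution	VIC	FAM	Failed	.
M9a	K	C	G	substitution	VIC	FAM	97.3	M9_ctrl
M9b	K	C	G	substitution	FAM	VIC	97.3	M9_ctrl
M20	L	A	G	substitution	VIC	FAM	94.3	.
M27	L1	C	G	substitution	VIC	FAM	94.7	.
M317	L2	GA	del	deletion	VIC	FAM	94.3	.
M357	L3	C	A	substitution	VIC	FAM	97.3	.
P256	M	G	A	substitution	VIC	FAM	97.7	.
M231	N	G	A	substitution	VIC	FAM	94.7	.
M128	N1a	ref	del	deletion	VIC	FAM	97.0	.
P43	N1b	G	A	substitution	VIC	FAM	96.6	.
P105	N1c	G	A	substitution	VIC	FAM	96.2	.
M214	NO	G	C	substitution	VIC	FAM	96.6	.
M119	O1a	A	C	substitution	VIC	FAM	99.2	.
P31	O2	T	C	substitution	VIC	FAM	95.8	.
M122	O3	T	C	substitution	VIC	FAM	98.9	.
M45	P	G	A	substitution	VIC	FAM	96.2	.
M242	Q	C	T	substitution	VIC	FAM	97.3	.
M207	R	A	G	substitution	VIC	FAM	95.5	.
M173	R1	A	C	substitution	VIC	FAM	93.2	.
SRY10831.2	R1a	G	A	substitution	VIC	FAM	99.6	.
M56	R1a1a	A	T	substitution	VIC	FAM	97.7	.
M157	R1a1b	A	C	substitution	VIC	FAM	98.1	.
M204	R1a1c	T	G	substitution	VIC	FAM	95.8	.
P98	R1a1d	C	T	substitution	VIC	FAM	Failed	.
PK5	R1a1e	C	T	substitution	VIC	FAM	95.8	.
M343	R1b	C	A	substitution	VIC	FAM	97.3	.
M18	R1b1a	ref	ins	insertion	VIC	FAM	96.6	.
P297	R1b1b	G	C	substitution	VIC	FAM	95.8	.
M73	R1b1b1	ref	del	deletion	VIC	FAM	96.2	.
M269	R1b1b2	C	T	substitution	VIC	FAM	96.2	.
L23	R1b1b2a	A	G	substitution	VIC	FAM	84.8	.
P311	R1b1b2a1	A	G	substitution	VIC	FAM	97.0	.
U106	R1b1b2a1a	C	T	substitution	VIC	FAM	97.3	.
U198	R1b1b2a1a1	G	A	substitution	VIC	FAM	98.5	.
P107	R1b1b2a1a2	G	A	substitution	VIC	FAM	Failed	.
P312	R1b1b2a1b	A	C	substitution	VIC	FAM	97.3	.
M65	R1b1b2a1b1	A	T	substitution	VIC	FAM	96.6	.
M153	R1b1b2a1b2	T	A	substitution	VIC	FAM	97.7	.
SRY2627	R1b1b2a1b3	C	T	substitution	VIC	FAM	97.3	.
U152	R1b1b2a1b4	C	T	substitution	VIC	FAM	97.0	.
M126	R1b1b2a1b4a	ref	del	deletion	VIC	FAM	97.3	.
M160	R1b1b2a1b4b	A	C	substitution	VIC	FAM	96.2	.
L21	R1b1b2a1b5	C	G	substitution	VIC	FAM	97.7	.
M37	R1b1b2a1b5a	C	T	substitution	VIC	FAM	87.9	.
M222	R1b1b2a1b5b	G	A	substitution	VIC	FAM	97.7	.
P66	R1b1b2a1b5c	G	A	substitution	VIC	FAM	98.1	.
M335	R1b1c	T	A	substitution	VIC	FAM	96.2	.
M124	R2	C	T	substitution	VIC	FAM	98.1	.
M70	T	A	C	substitution	VIC	FAM	97.0	.
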