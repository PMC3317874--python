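# Transcribed per-residue interface interaction energies (kcal/mol) for the
# palmitoylated mu-opioid receptor homodimer / cholesterol complex.
# The "total" column preserves the published rounded Total, which was rounded
# from full precision and may differ from coulombic+vdw by 0.01.
section	label	coulombic	vdw	total
row	T4.38	-0.01	-0.03	-0.04
row	P4.39	0.08	-0.02	0.06
row	R4.40	0.30	-0.31	-0.01
row	N4.41	-0.32	-1.06	-1.38
row	I4.44	-0.02	-3.56	-3.58
row	I4.45	0.09	-1.22	-1.13
row	V4.47	-0.06	-0.24	-0.31
row	C4.48	0.11	-1.49	-1.38
row	W4.50	0.03	-0.02	0.01
row	I4.51	0.18	-2.77	-2.58
row	L4.52	0.03	-0.11	-0.08
row	S4.54	0.03	-0.06	-0.03
row	A4.55	0.21	-2.11	-1.90
row	I4.56	0.11	-2.42	-2.32
row	G4.57	-0.03	0.00	-0.04
row	P4.59	0.01	-0.07	-0.06
chol_a_vs_b	CholA_vs_ProtomerB	0.07	-2.52	-2.44
chol_b_vs_a	CholB_vs_ProtomerA	0.10	-2.49	-2.39
protomer_subtotal	ProtomerAB	0.74	-15.50	-14.76
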