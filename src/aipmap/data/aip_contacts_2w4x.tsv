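contact_type	ligand_atom_type	protein_atom_type	ligand_aip_value	protein_aip_value	f	ddG_kJ_per_mol
	H.soft	C.ar	1.3	-1.5	0.5	-1.4
	N.2	C.2	-1.1	-0.5	0.5	-1.8
	H.soft	C.ar	1.2	-1.8	0.5	-1.3
H-bond	H.O	O.2.other	4.3	-5.5	1.0	-1.4
	C.2	C.ar	-0.4	-1.9	0.5	-1.3
	N.pl3.am	C.ar	2.1	-1.3	0.5	-0.4
H-bond	O.3.alcohol	H.O	-5.1	3.7	1.0	-0.5
	H.soft	S.3	1.3	0.0	0.5	-1.4
	H.soft	C.2	0.8	-1.7	0.5	-1.6
	H.soft	H.soft	1.0	0.3	1.0	-3.1
H-bond	H.O	O.2.am	4.3	-7.2	1.0	-3.8
H-bond	O.2.am	H.N	-4.4	2.6	1.0	0.0
	N.pl3.am	C.ar	1.4	-2.0	0.5	-1.1
	H.soft	H.soft	1.3	0.4	0.5	-1.2
	C.2	C.ar	0.3	-1.4	0.5	-1.8
	H.soft	C.ar	1.2	-1.7	0.5	-1.4
	H.soft	N.pl3.am	0.7	-0.4	0.5	-2.0
	H.soft	H.soft	0.7	0.3	0.5	-1.8
	H.soft	H.soft	1.0	0.9	1.0	-2.2
H-bond	O.3.alcohol	H.N	-3.4	2.6	1.0	0.0
	H.soft	S.3	1.3	-3.3	0.5	-0.5
H-bond	H.O	O.2.other	3.0	-5.5	1.0	-0.2
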