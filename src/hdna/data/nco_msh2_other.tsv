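# NCO-associated msh2 strand transfers, other patterns (octad mode)
# total_occurrence=35
kind	mode	pattern	occurrence	chromatid_assignment	printed_class
NCO	msh2	3:5	1	two-non-sister	other
NCO	msh2	2:6	8	single	other
NCO	msh2	3:5_2:6	5	single	other
NCO	msh2	4:4*_3:5	1	two-non-sister	other
NCO	msh2	2:6_1:7	1	two-sister	other
NCO	msh2	3:5_4:4_2:6	3	single	other
NCO	msh2	3:5_4:4_2:6	1	two-sister	other
NCO	msh2	6:2_4:4_6:2	1	single	other
NCO	msh2	3:5_4:4_4:4*	1	two-non-sister	other
NCO	msh2	5:3_4:4_3:5	2	two-non-sister	other
NCO	msh2	3:5_4:4_3:5*	1	two-sister	other
NCO	msh2	4:4*_3:5_4:4*	1	two-non-sister	other
NCO	msh2	3:5_2:6_4:4_3:5	1	single	other
NCO	msh2	2:6_3:5_2:6_3:5*	1	single	other
NCO	msh2	6:2_5:3_4:4_3:5	1	two-non-sister	other
NCO	msh2	5:3_4:4_5:3*_6:2_5:3*	1	single	other
NCO	msh2	3:5_4:4_2:6_3:5_2:6	1	single	other
NCO	msh2	3:5_4:4_3:5_2:6_3:5	1	single	other
NCO	msh2	5:3_4:4_3:5_4:4_3:5	1	two-non-sister	other
NCO	msh2	4:4*_5:3_6:2_5:3*_6:2_5:3*	1	two-non-sister	other
NCO	msh2	3:5_2:6_3:5_2:6_3:5_2:6_3:5_2:6_3:5_2:6	1	single	other
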