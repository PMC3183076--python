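# CO-associated msh2 strand transfer patterns (octad mode)
# The ">3" pattern aggregates the printed row of events with more than three
# successive DNA tracts (up to 8); individual patterns were not printed.
# total_occurrence=181
kind	mode	pattern	occurrence	chromatid_assignment	printed_class
CO	msh2	none	26	none	none
CO	msh2	2:6	26	single	single
CO	msh2	3:5	16	single	single
CO	msh2	4:4*	1	two-non-sister	two-non-sister
CO	msh2	3:5_2:6	15	single	single
CO	msh2	3:5_4:4	7	single	single
CO	msh2	2:6_4:4	5	single	single
CO	msh2	3:5_4:4*	4	two-non-sister	two-non-sister
CO	msh2	5:3_5:3*	1	single	single
CO	msh2	3:5_5:3	2	single	single
CO	msh2	5:3_2:6	1	single	single
CO	msh2	3:5_4:4_3:5	2	single	single
CO	msh2	2:6_4:4_2:6	4	single	single
CO	msh2	3:5_4:4_2:6	5	single	single
CO	msh2	2:6_3:5_4:4	2	single	single
CO	msh2	3:5_2:6_3:5*	3	two-non-sister	two-non-sister
CO	msh2	3:5_4:4_3:5*	2	two-non-sister	two-non-sister
CO	msh2	2:6_4:4*_3:5	1	two-non-sister	two-non-sister
CO	msh2	4:4*_3:5_3:5*	1	two-non-sister	two-non-sister
CO	msh2	5:3_5:3*_6:2	2	two-non-sister	two-non-sister
CO	msh2	3:5_4:4_5:3	2	single	single
CO	msh2	3:5_6:2_5:3	1	single	single
CO	msh2	2:6_3:5_5:3	1	single	single
CO	msh2	6:2_4:4_3:5	2	single	single
CO	msh2	>3	27	single	single
CO	msh2	>3	22	two-non-sister	two-non-sister
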