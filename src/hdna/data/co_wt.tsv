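# CO-associated strand transfers in the presence of Msh2 (tetrad mode)
# total_occurrence=282
kind	mode	pattern	occurrence	chromatid_assignment	printed_class
CO	wt	none	62	none	none
CO	wt	3:1	194	unspecified
CO	wt	3:1_2:2	8	unspecified
CO	wt	3:1_1:3	4	unspecified
CO	wt	3:1_2:2_3:1	11	unspecified
CO	wt	3:1_2:2_3:1*_2:2	1	unspecified
CO	wt	3:1_2:2_1:3_2:2*_1:3	1	unspecified
CO	wt	3:1_2:2_3:1_2:2_3:1_2:2_3:1	1	unspecified
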