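# NCO-associated strand transfers in the presence of Msh2 (tetrad mode)
# total_occurrence=65
kind	mode	pattern	occurrence	chromatid_assignment	printed_class
NCO	wt	3:1	53	unspecified
NCO	wt	3:1_1:3	1	unspecified
NCO	wt	3:1_2:2*	3	unspecified
NCO	wt	3:1_2:2_3:1	5	unspecified
NCO	wt	3:1_2:2*_3:1	1	unspecified
NCO	wt	3:1_2:2_3:1*	1	unspecified
NCO	wt	3:1_1:3_1:3*_2:2_1:3*	1	unspecified
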