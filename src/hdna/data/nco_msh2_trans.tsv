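# NCO-associated msh2 strand transfers, trans hDNA-like patterns (octad mode)
# total_occurrence=59
kind	mode	pattern	occurrence	chromatid_assignment	printed_class
NCO	msh2	3:5_3:5*	28	single	trans
NCO	msh2	3:5_4:4_3:5*	22	single	trans
NCO	msh2	3:5_2:6_3:5*	2	single	trans
NCO	msh2	3:5_4:4_3:5_3:5*	1	single	trans
NCO	msh2	5:3_4:4_5:3_5:3*	1	single	trans
NCO	msh2	3:5_3:5*_4:4_3:5*	1	single	trans
NCO	msh2	5:3_4:4_5:3*_4:4_5:3*	1	single	trans
NCO	msh2	5:3_4:4_5:3_4:4_5:3*	1	single	trans
NCO	msh2	3:5_4:4_3:5_4:4_3:5_3:5*	1	single	trans
NCO	msh2	5:3_4:4_6:2_5:3*_6:2_5:3*	1	single	trans
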