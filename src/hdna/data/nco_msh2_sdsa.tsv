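# NCO-associated msh2 strand transfers, SDSA-like patterns (octad mode)
# total_occurrence=75
kind	mode	pattern	occurrence	chromatid_assignment	printed_class
NCO	msh2	3:5	66	single	sdsa
NCO	msh2	3:5_4:4_3:5	5	single	sdsa
NCO	msh2	5:3_6:2_5:3	1	single	sdsa
NCO	msh2	3:5_4:4_3:5_4:4_3:5	1	single	sdsa
NCO	msh2	5:3_4:4_5:3_4:4_5:3	1	single	sdsa
NCO	msh2	3:5_2:6_3:5_2:6_3:5	1	single	sdsa
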