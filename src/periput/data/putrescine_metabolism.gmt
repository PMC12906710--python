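put_biosynthesis	putrescine metabolism	ODC1	AGMAT	PAOX
put_loss	putrescine metabolism	SRM	OAZ1	OAZ2	OAZ3	NQO1
put_transport	putrescine metabolism	SLC22A1	SLC22A2	SLC22A3	SLC7A1	ATP13A2	ATP13A3	GPC1
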