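sample_id	stage	embryo_id
MII_c1	MII	e1
MII_c2	MII	e2
zygote_c1	zygote	e3
2cell_c1	2cell	e4
4cell_c1	4cell	e5
8cell_c1	8cell	e6
16cell_c1	16cell	e7
32cell_c1	32cell	e8
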