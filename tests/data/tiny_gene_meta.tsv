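gene_id	category	is_reference	specific
Hnrnpr	reference	True	True
Ssu72	reference	True	True
Ube2e1	reference	True	True
Mat1	maternal factor	False	True
Zyg1	zygotic factor	False	True
Junk1	primer dimer	False	False
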