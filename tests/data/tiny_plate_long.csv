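SampleName,AssayName,CtValue,CtCall
MII_c1,Hnrnpr,20.0,Pass
MII_c2,Hnrnpr,20.0,Pass
zygote_c1,Hnrnpr,20.0,Pass
2cell_c1,Hnrnpr,20.0,Pass
4cell_c1,Hnrnpr,20.0,Pass
8cell_c1,Hnrnpr,20.0,Pass
16cell_c1,Hnrnpr,20.0,Pass
32cell_c1,Hnrnpr,20.0,Pass
MII_c1,Ssu72,19.0,Pass
MII_c2,Ssu72,19.0,Pass
zygote_c1,Ssu72,19.0,Pass
2cell_c1,Ssu72,19.0,Pass
4cell_c1,Ssu72,19.0,Pass
8cell_c1,Ssu72,19.0,Pass
16cell_c1,Ssu72,19.0,Pass
32cell_c1,Ssu72,19.0,Pass
MII_c1,Ube2e1,21.0,Pass
MII_c2,Ube2e1,21.0,Pass
zygote_c1,Ube2e1,21.0,Pass
2cell_c1,Ube2e1,21.0,Pass
4cell_c1,Ube2e1,21.0,Pass
8cell_c1,Ube2e1,21.0,Pass
16cell_c1,Ube2e1,21.0,Pass
32cell_c1,Ube2e1,21.0,Pass
MII_c1,Mat1,22.0,Pass
MII_c2,Mat1,23.0,Pass
zygote_c1,Mat1,23.0,Pass
2cell_c1,Mat1,24.0,Pass
4cell_c1,Mat1,26.0,Pass
8cell_c1,Mat1,28.0,Pass
16cell_c1,Mat1,999.0,Fail
32cell_c1,Mat1,999.0,Fail
MII_c1,Zyg1,999.0,Fail
MII_c2,Zyg1,999.0,Fail
zygote_c1,Zyg1,999.0,Fail
2cell_c1,Zyg1,25.0,Pass
4cell_c1,Zyg1,23.0,Pass
8cell_c1,Zyg1,22.0,Pass
16cell_c1,Zyg1,21.0,Pass
32cell_c1,Zyg1,21.0,Pass
MII_c1,Junk1,25.0,Pass
MII_c2,Junk1,25.0,Pass
zygote_c1,Junk1,25.0,Pass
2cell_c1,Junk1,25.0,Pass
4cell_c1,Junk1,25.0,Pass
8cell_c1,Junk1,25.0,Pass
16cell_c1,Junk1,25.0,Pass
32cell_c1,Junk1,25.0,Pass
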