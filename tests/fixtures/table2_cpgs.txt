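cg11538389
cg05410283
cg08937729
cg09853822
cg07352586
cg03077492
cg08213351
cg09163702
cg05879380
cg00026803
cg056612821
cg11791670
cg04966851
cg00316875
cg07400328
cg05650719
cg03531512
cg07991241
cg11175310
cg02993069
cg00010992
cg11186962
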