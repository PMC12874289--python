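name	formula
aminophenol	C6H7NO
glycine	C2H5NO2
taurine	C2H7NO3S
alanine	C3H7NO2
serine	C3H7NO3
aspartate	C4H7NO4
glutamate	C5H9NO4
ornithine	C5H12N2O2
lysine	C6H14N2O2
citrulline	C6H13N3O3
putrescine	C4H12N2
cadaverine	C5H14N2
tyrosine	C9H11NO3
phenylalanine	C9H11NO2
tryptophan	C11H12N2O2
histidine	C6H9N3O2
arginine	C6H14N4O2
ethanolamine	C2H7NO
water	H2O
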