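breed,population,gene,allele,count,n_genotyped
BULT,,TYRP1,B,94,50
BULT,,TYRP1,bs,3,50
BULT,,TYRP1,bc,3,50
SKIP,UK,MC1R,E,6,6
SKIP,UK,MC1R,e,6,6
GDANE,,CBD103,KB_kbr,66,50
GDANE,,CBD103,ky,34,50
GDANE,,MITF,S,94,50
GDANE,,MITF,sp,6,50
GDANE,,PSMB7,H,79,50
GDANE,,PSMB7,h,21,50
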