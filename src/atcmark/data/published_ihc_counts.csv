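cohort,tumor_class,marker,n_total,n_positive
test,ATC,IGF2BP1,10,10
test,PTC,IGF2BP1,6,0
test,FTC,IGF2BP1,6,0
TMA_I,ATC,IGF2BP1,20,14
TMA_I,PDTC,IGF2BP1,18,1
TMA_I,PTC,IGF2BP1,82,0
TMA_I,FTC,IGF2BP1,29,0
TMA_II,ATC,IGF2BP1,6,3
TMA_II,PTC,IGF2BP1,44,0
TMA_II,FTC,IGF2BP1,20,0
test,ATC,MAGEA3,10,10
test,PTC,MAGEA3,6,0
test,FTC,MAGEA3,6,0
TMA_I,ATC,MAGEA3,20,7
TMA_I,PDTC,MAGEA3,18,0
TMA_I,PTC,MAGEA3,82,0
TMA_I,FTC,MAGEA3,29,0
TMA_II,ATC,MAGEA3,6,1
TMA_II,PTC,MAGEA3,44,0
TMA_II,FTC,MAGEA3,20,0
test,ATC,MYC,10,9
test,PTC,MYC,6,5
test,FTC,MYC,6,3
TMA_I,ATC,MYC,20,15
TMA_I,PDTC,MYC,18,2
TMA_I,PTC,MYC,82,1
TMA_I,FTC,MYC,29,5
TMA_II,ATC,MYC,6,2
TMA_II,PTC,MYC,44,0
TMA_II,FTC,MYC,20,0
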