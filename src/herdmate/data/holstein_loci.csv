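name,maf,value,lethal
Brachyspina,0.0276,150,true
HH1,0.0192,40,true
HH2,0.0166,40,true
HH3,0.0295,40,true
HH4,0.0037,40,true
HH5,0.0222,40,true
BLAD,0.0025,150,true
CVM,0.0137,70,true
DUMPS,0.0001,40,true
Mulefoot,0.0007,150,true
Horned,0.9929,40,false
Red coat color,0.0542,-20,false
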