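mutation,case_id,css,note
T158M,I,36,
T158M,II,43,
T158M,III,31,
T158M,IV,47,
R133C,V,37,
F157I,VI,37,
N126I,VII,36,
P152H,VIII,18,
R167W,IX,12,
A140V,X,10,Natural History Study value; literature range 1-5 kept as metadata
P152A,XI,1,
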