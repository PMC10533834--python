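hmgb2a
hmgb2b
cdk1
nusap1
ube2c
birc5a
birc5b
tpx2
top2a
ndc80
cks2
nuf2
cks1b
mki67
tmpoa
tmpob
cenpf
tacc3
smc4
ccnb2
ckap2l
aurkb
bub1
kif11
anp32e
tubb4b
gtse1
kif20ba
cdca3
jpt1a
cdc20
ttk
cdc25b
kif2c
rangap1a
rangap1b
ncapd2
dlgap5
cdca8
ect2
kif23
hmmr
aurka
anln
lbr
ckap5
cenpe
ctcf
nek2
g2e3
gas2l3
cbx5
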