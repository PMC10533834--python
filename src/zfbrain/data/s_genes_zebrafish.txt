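mcm5
pcna
tyms
fen1
mcm2
mcm4
rrm1
unga
ungb
gins2
mcm6
cdca7a
cdca7b
dtl
prim1
uhrf1
cenpu
hells
rfc2
rpa2
nasp
rad51ap1
gmnn
wdr76
slbp
slbp2
ccne2
ubr7
pold3
msh2
atad2
atad2b
rad51
rad51b
rad51c
rad51d
rrm2
rrm2b
cdc45
cdc6
exo1
tipin
dscc1
blm
casp8ap2
usp1
pola1
chaf1b
brip1
e2f8
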