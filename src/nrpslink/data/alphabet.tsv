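# Default supported-residue alphabet (58 residues): the 20 proteinogenic
# amino acids plus common nonribosomal monomers.  Users may replace this
# file; names are opaque lower-case identifiers, one per line, with an
# optional tab-separated background-frequency column.
ala
arg
asn
asp
cys
gln
glu
gly
his
ile
leu
lys
met
phe
pro
ser
thr
trp
tyr
val
orn
horn
fohorn
dab
dap
aad
abu
dhb
sal
pip
hpg
dhpg
bht
bala
bmt
kyn
hse
hty
cit
hyp
end
cap
dht
dha
dhab
ival
aib
hiv
lac
phg
ahp
hasp
hasn
hleu
vol
pheol
cysa
anth
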