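activ
affin
alloster
associ
attach
between
bind
bond
bound
catalyt
chang
cleavag
cofactor
complex
conform
cooper
conjug
conserv
contact
cycliz
delet
diminish
direct
domain
downstream
enhanc
enzym
facilit
growth
increas
induc
induct
inhibit
interact
interfac
involv
linkag
mechan
metabol
modifi
modul
phosphoryl
positio
preferenti
proxim
reassoci
receptor
recognit
redox
regulatori
signal
specif
stabil
stimul
substrat
suppress
surfac
target
transform
trigger
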