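affin
alloster
associ
attach
bind
bond
bound
catalyt
cleavag
complex
conform
conserv
cooper
contact
cycliz
delet
diminish
domain
enhanc
enzym
facilit
increas
induc
inhibit
interact
interfac
linkag
mechan
modifi
modul
preferenti
recognit
regulatori
specif
stabil
substrat
surfac
target
transform
trigger
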