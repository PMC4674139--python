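affin
alloster
associ
attach
bind
bond
bound
catalyt
chang
cleavag
complex
conform
conserv
cooper
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
inhibit
interact
interfac
involv
linkag
mechan
metabol
modifi
modul
preferenti
reassoci
recognit
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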