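affin
alloster
associ
attach
bind
bond
bound
cleavag
complex
conform
conserv
contact
cooper
domain
induc
interfac
interact
linkag
mechan
modifi
modul
preferenti
recognit
regulatori
specif
stabil
surface
substrat
target
transform
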