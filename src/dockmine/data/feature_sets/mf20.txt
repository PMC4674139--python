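alloster
bind
bond
bound
cleavag
complex
conform
contact
conserv
domain
induc
interfac
interact
mechan
modul
preferenti
recognit
specif
stabi
surface
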