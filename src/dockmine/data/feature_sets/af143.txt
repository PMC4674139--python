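polymorph
interfac
energi
bond
free
antibodi
beta
phenotyp
patient
promot
light
degre
conjug
gene
affin
label
diseas
filament
affect
signal
ca2+
crystal
properti
complex
interact
resist
level
valu
detect
membran
contain
contribut
inclu
terminu
produc
genera
regul
shown
examin
transcript
normal
lower
time
base
stabil
express
critic
phosphoryl
subunit
function
assai
peptid
catalyt
surfac
enhanc
investig
format
positio
determin
residu
bind
loop
rate
effici
report
factor
molecul
inhibit
prolifer
deriv
sequenc
alter
singl
mediat
structur
purifi
induc
depend
dna
reveal
sensit
receptor
compar
model
cleavag
via
product
target
variant
specif
loss
growth
potenti
requir
essenti
caus
decreas
low
substrat
associ
mechan
conform
fold
contrast
similar
type
involv
found
novel
region
exhibit
wild
vitro
observ
develop
fragment
famil
conserv
cell
identifi
stud
reduc
provid
demonstr
acid
data
link
effect
presenc
activ
result
role
domain
chain
enzym
form
alpha
index
site
increas
suggest
mutant
protein
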