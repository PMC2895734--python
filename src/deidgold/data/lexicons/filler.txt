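Pat
inkommer
med
besvär
sedan
tidigare
känd
hypertoni
söker
akut
för
buksmärta
yrsel
feber
hosta
andfåddhet
bedöms
stabil
planeras
uppföljning
via
kontakt
tas
anhörig
informerad
om
läget
ordineras
tabl
mot
smärta
vid
behov
återbesök
nästa
vecka
remiss
skickas
till
status
gott
och
opåverkad
i
vila
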