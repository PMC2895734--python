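# Abbreviations whose trailing period is part of the token.
univ
avd
dr
doc
sjukh
vc
mott
pat
ssk
t.ex
bl.a
p.g.a
enl
kl
tel
jour
med
kir
ort
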