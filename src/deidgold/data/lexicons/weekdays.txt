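måndag
tisdag
onsdag
torsdag
fredag
lördag
söndag
måndagen
tisdagen
onsdagen
torsdagen
fredagen
lördagen
söndagen
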