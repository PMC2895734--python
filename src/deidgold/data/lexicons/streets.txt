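Storgatan 1
Kvarnvägen 12
Björkallén 7
Strandstigen 3 B
Almgatan 24
Solviksvägen 118
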