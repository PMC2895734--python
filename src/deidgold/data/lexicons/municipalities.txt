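Solviks kommun
Norrbacka kommun
Ekefors kommun
Sundby kommun
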