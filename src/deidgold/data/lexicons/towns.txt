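Solvik
Norrbacka
Hagvik
Ekefors
Lindesta
Björkhult
Sundby
Tallåsen
Granlund
Västerhed
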