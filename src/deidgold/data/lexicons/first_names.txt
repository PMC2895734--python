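Anna
Erik
Karin
Lars
Maja
Olof
Sara
Nils
Elin
Gustav
Ingrid
Per
Tove
Axel
Greta
Henrik
Lova
Sixten
Märta
Vilgot
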