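Svensson
Lindqvist
Bergström
Åkerlund
Norrman
Sjöberg
Holmgren
Dalgren
Vikström
Ekelöf
Franzén
Hällström
Lundmark
Öberg
Nystedt
Almkvist
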