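svensk
finsk
norsk
dansk
isländsk
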