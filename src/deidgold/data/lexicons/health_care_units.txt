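Karlsta Universitetssjukhuset, Hagvik
Karlsta Univ. Sjukh, Hagvik
Karlsta/Hagvik
Avd. 11 på Karlsta
Vårdcentralen Solvik
Solviks VC
Norrbacka sjukhus
Akutmottagningen Karlsta
Geriatrikkliniken Ekefors
Ortopedkliniken Norrbacka sjukhus
S:t Eriksgårdens vårdcentral
Medicinkliniken Karlsta, avd 4
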