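# 10 functional partners predicted at very high confidence (score >= 0.9)
Cbfb
Cobl
Limk1
Mapkapk2
Mdh1
Mdh2
Psma8
Psmb1
Psmb2
RSA-14-44
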