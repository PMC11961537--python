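RES
1b:b-dglc-HEX-1:5
2s:n-acetyl
LIN
1:1d(2+1)2n
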