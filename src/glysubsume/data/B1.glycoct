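RES
1b:x-HEX-x:x
2s:n-acetyl
3b:x-HEX-x:x
LIN
1:1d(2+1)2n
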