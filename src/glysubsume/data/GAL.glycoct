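RES
1b:b-dgal-HEX-1:5
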