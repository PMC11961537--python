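name	glycoct_descriptor
Glc	dglc-HEX
Gal	dgal-HEX
Man	dman-HEX
Hex	HEX
Fuc	lgal-HEX|6:d
Fuc-d	dgal-HEX|6:d
dHex	HEX|6:d
Neu	dgro-dgal-NON|1:a|2:keto|3:d
NonAcid	NON|1:a|2:keto|3:d
GlcA	dglc-HEX|6:a
HexA	HEX|6:a
Xyl	dxyl-PEN
Ara	lara-PEN
Pent	PEN
n-acetyl	s:n-acetyl
n-glycolyl	s:n-glycolyl
amino	s:n
sulfate	s:sulfate
phosphate	s:phosphate
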