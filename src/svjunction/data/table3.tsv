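case	cma_pattern	wgs_pattern
P2109_190	DEL-DIP-DEL	DEL-INV-DEL
P72	DEL-DIP-DEL	DEL-INV-DEL
P2109_302	DEL	DEL-INV-DEL
P2109_123	DEL	DEL-INV-DEL
P2109_188	DEL-DIP-DEL	DEL-INV-DEL-INV-DEL
P81	DEL-DIP-DEL-DIP-DEL	DEL-N-DEL-INV-DEL-INV-DEL
P2046_133	DEL-DIP-DEL	DEL-INV-INV-INV-DEL-INV-DEL-N-DEL-N-DEL-N
P00	DEL-DIP-DEL-DIP-DEL-DIP-DEL	DEL-INV-DEL-INV-DEL-INV-DEL-INV-DEL-INV-DEL-N-DEL
P06	DUP-DIP-DUP	DUP-N-DUP
P4855_511	DUP-DIP-DUP	DUP-N-DUP
P2109_150	DUP	DUP-N-DUP
P2109_151	DUP	DUPinv-N-DUP
P74	DUP-DIP-DUP	DUP-N-DUP
P4855_512	DUP-DIP-DUP	DUPinv-N-DUP
P5513_206	DUP-DIP-DUP-DIP-DUP-DIP-DUP	DUPinv-N-DUP-N-DUP-N-DUPinv-N-DUP
P2109_162	DEL-DIP-DEL-DIP-DUP	DEL-INV-DEL-N-DEL-N-DUP
P5513_116	DUP-DIP-DEL	DUP-N-DUP-N-DEL
P5371_204	DUP-DIP-DEL-DIP-DUP	DUP-N-DEL-N-DEL-N-DUP
P2109_185	DEL-DUP-DEL-DUP-DIP-DUP	DEL-N-DUP-DEL-N-DUP-N-DUP
P2109_176	DEL-DUP-DEL	DEL-INV-DEL-N-DEL-DUP-DEL-DUP
P1426_301	DEL-DIP-DUP-DIP-DUP-DIP-DEL-DIP-DUP-DIP-DEL-DIP-DEL-DUP	DEL-N-DUP-N-DUP-N-DUP-N-DUP-N-DEL-INV-DUP-INV-DUP-N-DEL-N-DEL-N-DUP-N-DUP-N-DUP
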