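case	mechanism
P2109_190	chromothripsis
P72	chromothripsis
P2109_302	chromothripsis
P2109_123	chromothripsis
P2109_188	chromothripsis
P81	chromothripsis
P00	chromothripsis
P06	chromoanasynthesis
P4855_511	chromoanasynthesis
P2109_150	chromoanasynthesis
P2109_151	chromoanasynthesis
P74	chromoanasynthesis
P4855_512	chromoanasynthesis
P5513_206	chromoanasynthesis
P2109_162	chromoanasynthesis
P5513_116	chromoanasynthesis
P5371_204	chromoanasynthesis
P2109_185	ambiguous
P2109_176	ambiguous
P2046_133	ambiguous
P1426_301	ambiguous
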