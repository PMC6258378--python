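case	mechanism	reason
P2109_188	chromothripsis	Large junction inserts attributed to alt-NHEJ stitching of shattered fragments; expert call places the case with the shattering-type events despite insert sizes above the ambiguity threshold.
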