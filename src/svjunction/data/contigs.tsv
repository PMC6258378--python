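chromosome	length
1	249250621
2	243199373
4	191154276
5	180915260
7	159138663
11	135006516
13	115169878
14	107349540
16	90354753
17	81195210
21	48129895
X	155270560
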