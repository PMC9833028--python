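# Built-in bead-sandwich ELISA magnet program
# one command per line; layers T/N/M/B, keypoints 1-9
N1 to N1
INCUBATE 1 900 50
HOLD B1 20
B1 to B2
INCUBATE 2 60 3
HOLD B2 20
B2 to B3
INCUBATE 3 60 3
HOLD B3 20
B3 to B4
INCUBATE 4 900 50
HOLD B4 20
B4 to B5
INCUBATE 5 60 3
HOLD B5 20
B5 to B6
INCUBATE 6 60 3
HOLD B6 20
B6 to B7
INCUBATE 7 60 3
HOLD B7 20
B7 to B8
INCUBATE 8 300 3
HOLD B8 20
B8 to B9
HOLD B9 20
B9 to B8
MIX 8 3
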