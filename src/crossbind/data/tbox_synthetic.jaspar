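>SYNTH_TBOX synthetic T-box-like motif (not a database matrix)
A  [ 82   3   4   2   5  78   6  80  70  12 ]
C  [  6   4   3   5  80   8   5   6  10  14 ]
G  [  7  88   5  85   7   6   4   8  12  60 ]
T  [  5   5  88   8   8   8  85   6   8  14 ]
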