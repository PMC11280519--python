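# Lorenz-grid segment mask: 31x31 labels 0..12, row 0 = most negative y bin
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3 11 11 11 11 11  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3  7  7  7  7  7  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3  7  7  7  7  7  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3  7  7  7  7  7  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3  7  7  7  7  7  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3  7  7  7  7  7  4  4  4  4  4  4  4  4  4  4  4  4  4
 3  3  3  3  3  3  3  3  3  3  3  3  3  7  7  7  7  7  4  4  4  4  4  4  4  4  4  4  4  4  4
10 10 10 10 10 10 10  6  6  6  6  6  6  0  0  0  0  0  8  8  8  8  8  8 12 12 12 12 12 12 12
10 10 10 10 10 10 10  6  6  6  6  6  6  0  0  0  0  0  8  8  8  8  8  8 12 12 12 12 12 12 12
10 10 10 10 10 10 10  6  6  6  6  6  6  0  0  0  0  0  8  8  8  8  8  8 12 12 12 12 12 12 12
10 10 10 10 10 10 10  6  6  6  6  6  6  0  0  0  0  0  8  8  8  8  8  8 12 12 12 12 12 12 12
10 10 10 10 10 10 10  6  6  6  6  6  6  0  0  0  0  0  8  8  8  8  8  8 12 12 12 12 12 12 12
 2  2  2  2  2  2  2  2  2  2  2  2  2  5  5  5  5  5  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  5  5  5  5  5  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  5  5  5  5  5  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  5  5  5  5  5  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  5  5  5  5  5  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  5  5  5  5  5  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
 2  2  2  2  2  2  2  2  2  2  2  2  2  9  9  9  9  9  1  1  1  1  1  1  1  1  1  1  1  1  1
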