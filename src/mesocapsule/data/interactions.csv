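species,N1,N2,O1,O2,C1,C2,S,W
N1,25,,,,,,,
N2,25.92,25,,,,,,
O1,27.47,30.81,25,,,,,
O2,44.23,51.46,31.06,25,,,,
C1,29.05,26.08,36.27,61.69,25,,,
C2,25.49,25.01,29.65,46.44,25.16,25,,
S,31.77,36.46,25.88,27,43.43,34.17,25,
W,95.99,106.18,57.89,35.74,121.98,87.94,44.73,25
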