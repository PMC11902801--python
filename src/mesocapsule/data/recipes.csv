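label,H2O,Cts,Alg,MC,Citral
Cts (1),98.87,1.13,0,0,0
Cts (2),98.50,1.50,0,0,0
Cts (3),98.13,1.87,0,0,0
Cts (4),97.77,2.23,0,0,0
Cts (5),97.40,2.60,0,0,0
Cts-Citral (1),98.31,1.12,0,0,0.57
Cts-Citral (2),97.94,1.49,0,0,0.57
Cts-Citral (3),97.58,1.86,0,0,0.56
Cts-Citral (4),97.22,2.22,0,0,0.56
Cts-Citral (5),96.86,2.58,0,0,0.56
Alg (1),98.28,0,1.72,0,0
Alg (2),98.12,0,1.88,0,0
Alg (3),97.95,0,2.05,0,0
Alg (4),97.78,0,2.22,0,0
Alg (5),97.61,0,2.39,0,0
Alg-Citral (1),97.73,0,1.71,0,0.56
Alg-Citral (2),97.56,0,1.87,0,0.56
Alg-Citral (3),97.40,0,2.04,0,0.56
Alg-Citral (4),97.23,0,2.21,0,0.56
Alg-Citral (5),97.07,0,2.37,0,0.56
Alg-Cts (1),96.60,0.13,3.27,0,0
Alg-Cts (2),96.56,0.17,3.27,0,0
Alg-Cts (3),96.52,0.21,3.27,0,0
Alg-Cts (4),96.48,0.25,3.27,0,0
Alg-Cts (5),96.44,0.30,3.27,0,0
Alg-Cts-Citral (1),96.07,0.13,3.25,0,0.55
Alg-Cts-Citral (2),96.03,0.17,3.25,0,0.55
Alg-Cts-Citral (3),95.98,0.21,3.25,0,0.55
Alg-Cts-Citral (4),95.94,0.25,3.25,0,0.55
Alg-Cts-Citral (5),95.90,0.30,3.25,0,0.55
Alg-MC (1),98.22,0,1.66,0.12,0
Alg-MC (2),98.16,0,1.66,0.17,0
Alg-MC (3),98.11,0,1.66,0.23,0
Alg-MC (4),98.05,0,1.66,0.29,0
Alg-MC (5),97.99,0,1.66,0.35,0
Alg-MC-Citral (1),97.67,0,1.65,0.12,0.56
Alg-MC-Citral (2),97.61,0,1.65,0.17,0.56
Alg-MC-Citral (3),97.55,0,1.65,0.23,0.56
Alg-MC-Citral (4),97.50,0,1.65,0.29,0.56
Alg-MC-Citral (5),97.44,0,1.65,0.35,0.56
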