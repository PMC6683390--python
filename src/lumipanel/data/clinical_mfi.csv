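sample_id,donor_id,bead_id,mfi,role
S2,G1,GPIaIIa,83.59,test
S2,G1,GPIbaIX,414.37,test
S2,G1,HLA,1399,test
S2,G1,GPIIbIIIa,72.18,test
S2,G2,GPIaIIa,89.7,test
S2,G2,GPIbaIX,468.21,test
S2,G2,HLA,438.5,test
S2,G2,GPIIbIIIa,108.04,test
S2,G3,GPIaIIa,52.42,test
S2,G3,GPIbaIX,71.95,test
S2,G3,HLA,334,test
S2,G3,GPIIbIIIa,186.68,test
S2,G4,GPIaIIa,46.49,test
S2,G4,GPIbaIX,69.51,test
S2,G4,HLA,1442,test
S2,G4,GPIIbIIIa,58.83,test
S3,G1,GPIaIIa,71.05,test
S3,G1,GPIbaIX,36.19,test
S3,G1,HLA,1390,test
S3,G1,GPIIbIIIa,70.6,test
S3,G2,GPIaIIa,57.32,test
S3,G2,GPIbaIX,68.15,test
S3,G2,HLA,2469,test
S3,G2,GPIIbIIIa,74.08,test
S3,G3,GPIaIIa,83.57,test
S3,G3,GPIbaIX,43.42,test
S3,G3,HLA,2776.5,test
S3,G3,GPIIbIIIa,111.12,test
S3,G4,GPIaIIa,941.9,test
S3,G4,GPIbaIX,71.25,test
S3,G4,HLA,1395,test
S3,G4,GPIIbIIIa,71.52,test
T5,G1,GPIaIIa,56.06,test
T5,G1,GPIbaIX,21.63,test
T5,G1,HLA,45.19,test
T5,G1,GPIIbIIIa,3430.3,test
T5,G2,GPIaIIa,59.48,test
T5,G2,GPIbaIX,43.65,test
T5,G2,HLA,116.05,test
T5,G2,GPIIbIIIa,1053.89,test
T5,G3,GPIaIIa,69.32,test
T5,G3,GPIbaIX,53.31,test
T5,G3,HLA,71.13,test
T5,G3,GPIIbIIIa,1318.2,test
T5,G4,GPIaIIa,33.28,test
T5,G4,GPIbaIX,36.64,test
T5,G4,HLA,45.39,test
T5,G4,GPIIbIIIa,3997.51,test
S7,G1,GPIaIIa,1402.07,test
S7,G1,GPIbaIX,39.17,test
S7,G1,HLA,109.89,test
S7,G1,GPIIbIIIa,1355.66,test
S7,G2,GPIaIIa,1410.06,test
S7,G2,GPIbaIX,34.86,test
S7,G2,HLA,111.47,test
S7,G2,GPIIbIIIa,1406.88,test
S7,G3,GPIaIIa,1114.12,test
S7,G3,GPIbaIX,40.45,test
S7,G3,HLA,33.44,test
S7,G3,GPIIbIIIa,1297.48,test
S7,G4,GPIaIIa,1498.5,test
S7,G4,GPIbaIX,79.59,test
S7,G4,HLA,106.75,test
S7,G4,GPIIbIIIa,1810.53,test
T8,G1,GPIaIIa,33.77,test
T8,G1,GPIbaIX,41.91,test
T8,G1,HLA,103.64,test
T8,G1,GPIIbIIIa,1347.68,test
T8,G2,GPIaIIa,52.63,test
T8,G2,GPIbaIX,90.44,test
T8,G2,HLA,3675.49,test
T8,G2,GPIIbIIIa,1764.84,test
T8,G3,GPIaIIa,52.21,test
T8,G3,GPIbaIX,47.67,test
T8,G3,HLA,2065.35,test
T8,G3,GPIIbIIIa,92.82,test
T8,G4,GPIaIIa,51.73,test
T8,G4,GPIbaIX,37.52,test
T8,G4,HLA,1078.52,test
T8,G4,GPIIbIIIa,1153.1,test
S9,G1,GPIaIIa,76.06,test
S9,G1,GPIbaIX,79.44,test
S9,G1,HLA,559.08,test
S9,G1,GPIIbIIIa,876.67,test
S9,G2,GPIaIIa,76.41,test
S9,G2,GPIbaIX,69.5,test
S9,G2,HLA,5511.44,test
S9,G2,GPIIbIIIa,107.48,test
S9,G3,GPIaIIa,61.12,test
S9,G3,GPIbaIX,79,test
S9,G3,HLA,1961.17,test
S9,G3,GPIIbIIIa,785.68,test
S9,G4,GPIaIIa,69.75,test
S9,G4,GPIbaIX,83.96,test
S9,G4,HLA,3080.16,test
S9,G4,GPIIbIIIa,976.73,test
T10,G1,GPIaIIa,69.8,test
T10,G1,GPIbaIX,23.18,test
T10,G1,HLA,71.49,test
T10,G1,GPIIbIIIa,77.42,test
T10,G2,GPIaIIa,74.64,test
T10,G2,GPIbaIX,38.32,test
T10,G2,HLA,69.92,test
T10,G2,GPIIbIIIa,44.98,test
T10,G3,GPIaIIa,70.63,test
T10,G3,GPIbaIX,31.47,test
T10,G3,HLA,69.48,test
T10,G3,GPIIbIIIa,97.1,test
T10,G4,GPIaIIa,1979.27,test
T10,G4,GPIbaIX,80.06,test
T10,G4,HLA,78.05,test
T10,G4,GPIIbIIIa,54.36,test
S11,G1,GPIaIIa,50.8,test
S11,G1,GPIbaIX,47.89,test
S11,G1,HLA,28.64,test
S11,G1,GPIIbIIIa,423.74,test
S11,G2,GPIaIIa,56.66,test
S11,G2,GPIbaIX,71.67,test
S11,G2,HLA,37.95,test
S11,G2,GPIIbIIIa,1022.23,test
S11,G3,GPIaIIa,93.93,test
S11,G3,GPIbaIX,80.44,test
S11,G3,HLA,64.35,test
S11,G3,GPIIbIIIa,1248.52,test
S11,G4,GPIaIIa,43.16,test
S11,G4,GPIbaIX,35.45,test
S11,G4,HLA,72.41,test
S11,G4,GPIIbIIIa,1203.06,test
S12,G1,GPIaIIa,35.4,test
S12,G1,GPIbaIX,22.88,test
S12,G1,HLA,3135.34,test
S12,G1,GPIIbIIIa,91.55,test
S12,G2,GPIaIIa,41.92,test
S12,G2,GPIbaIX,74.05,test
S12,G2,HLA,14619.87,test
S12,G2,GPIIbIIIa,130.06,test
S12,G3,GPIaIIa,31.82,test
S12,G3,GPIbaIX,68.35,test
S12,G3,HLA,11924.19,test
S12,G3,GPIIbIIIa,85.82,test
S12,G4,GPIaIIa,54.81,test
S12,G4,GPIbaIX,29.88,test
S12,G4,HLA,9249.19,test
S12,G4,GPIIbIIIa,83.82,test
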