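dataset,IFSVM,ACFSVM,GFSVM,EFTWSVM,RFLSTSVM,FSVM-BD,FSVM-WD,RIFSVM
Liver,69.90,66.21,65.96,68.47,68.88,68.84,65.09,71.34
Seed,89.29,93.89,92.50,93.39,93.75,87.50,91.01,94.64
Wine,88.89,96.24,93.80,91.79,88.89,94.44,88.46,98.08
Haberman,62.08,62.88,63.23,64.10,68.10,68.33,66.32,69.17
Glass,81.28,77.82,81.28,70.64,71.82,83.33,80.13,83.33
Vehicle,96.66,94.99,98.14,96.68,96.66,97.94,98.72,98.72
Abalone,94.34,94.92,95.69,90.66,92.38,92.23,94.12,96.08
Ecoli,90.36,92.45,93.50,93.70,94.16,92.86,86.46,95.50
Balance,88.00,80.26,74.22,74.64,75.61,100.00,100.00,100.00
Libra,92.50,95.13,87.05,91.98,93.38,92.35,87.50,98.38
Yeast,65.30,70.14,67.28,62.04,70.00,62.87,65.61,67.71
Yeast1,73.82,85.03,84.04,82.11,83.19,79.99,80.82,85.61
Yeast2,85.61,89.81,89.28,89.46,88.95,89.73,90.43,93.91
Yeast3,92.04,85.13,85.13,82.51,82.28,90.00,90.00,93.37
Yeast4,83.95,83.09,83.37,83.24,83.17,80.89,80.89,84.15
Yeast5,61.96,70.31,70.77,70.60,67.91,68.53,63.94,70.91
Block,91.12,94.11,93.18,93.87,94.05,89.40,87.92,94.94
Block1,93.46,93.88,94.13,93.59,92.87,90.12,92.64,93.28
Block2,82.20,93.48,89.97,93.40,93.72,89.59,86.75,93.09
Block3,86.60,88.30,84.59,84.13,83.21,84.40,75.73,89.43
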