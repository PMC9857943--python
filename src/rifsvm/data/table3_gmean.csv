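dataset,IFSVM,ACFSVM,GFSVM,EFTWSVM,RFLSTSVM,FSVM-BD,FSVM-WD,RIFSVM
Liver,67.82,60.10,64.48,66.52,65.85,67.47,64.33,69.48
Seed,89.21,93.62,92.44,93.65,93.33,87.04,91.05,94.63
Wine,88.19,96.17,93.24,91.35,88.19,94.28,87.71,98.06
Haberman,57.01,62.43,61.57,63.65,67.96,65.83,62.36,69.13
Glass,79.96,77.17,79.95,69.30,69.82,81.65,80.14,81.65
Vehicle,96.64,94.98,98.14,96.63,96.64,97.94,98.71,98.71
Abalone,94.25,94.83,95.59,90.64,92.24,92.15,93.93,96.00
Ecoli,90.24,92.21,93.46,93.42,94.14,92.58,85.53,95.46
Balance,87.42,77.78,68.34,70.39,74.47,100.00,100.00,100.00
Libra,91.96,95.03,86.21,90.69,92.93,91.81,86.60,98.29
Yeast,60.95,70.11,68.42,54.89,69.74,60.45,60.89,65.51
Yeast1,71.44,84.83,83.16,80.68,83.04,77.81,78.83,84.95
Yeast2,84.95,89.43,88.80,88.96,88.75,89.57,90.38,93.83
Yeast3,91.93,84.02,84.02,80.65,81.02,89.44,89.56,93.31
Yeast4,83.01,81.54,81.76,83.06,82.09,78.78,78.78,83.30
Yeast5,49.73,68.07,65.04,64.92,60.27,61.14,53.27,68.76
Block,90.86,94.06,93.08,93.76,94.23,89.03,87.32,94.73
Block1,93.28,93.78,94.05,93.47,92.66,89.73,92.41,93.09
Block2,80.43,93.44,89.57,93.33,93.71,87.82,85.80,93.06
Block3,85.67,87.69,83.62,82.98,81.78,74.72,71.97,89.11
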