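dataset,IFSVM,ACFSVM,GFSVM,EFTWSVM,RFLSTSVM,FSVM-BD,FSVM-WD,RIFSVM
Liver,62.08,67.30,58.00,61.55,60.41,61.54,58.18,64.00
Seed,85.71,91.20,89.40,89.42,89.53,84.62,88.89,92.86
Wine,87.50,93.55,91.58,88.50,87.50,94.12,75.00,94.71
Haberman,42.86,47.24,46.43,48.45,52.72,53.33,50.00,54.12
Glass,60.95,40.61,62.67,32.22,33.67,80.00,72.30,80.00
Vehicle,94.87,90.82,96.85,95.45,94.91,96.20,98.70,98.70
Abalone,84.49,84.84,85.55,78.62,79.27,82.62,81.25,86.67
Ecoli,75.00,77.03,83.67,82.83,81.15,73.68,82.22,85.72
Balance,77.78,28.46,33.58,26.81,28.29,100.00,100.00,100.00
Libra,91.43,62.44,79.28,82.22,87.30,89.21,85.71,93.02
Yeast,49.31,57.43,52.82,42.57,57.29,46.81,49.65,53.75
Yeast1,59.52,67.53,70.77,70.86,56.82,67.83,57.49,72.73
Yeast2,72.73,80.72,82.81,84.21,70.50,75.00,70.77,85.71
Yeast3,78.56,76.92,76.92,75.24,63.81,88.89,88.89,81.82
Yeast4,66.67,63.55,69.17,58.96,59.69,66.67,66.67,75.00
Yeast5,33.33,34.21,44.00,40.80,39.23,41.88,36.36,46.15
Block,83.07,82.87,83.26,79.96,81.02,80.18,80.37,84.96
Block1,87.60,79.15,77.69,81.23,77.79,79.17,86.15,87.64
Block2,65.22,65.29,64.58,65.98,63.20,63.34,80.95,65.37
Block3,78.16,50.19,49.22,53.99,53.39,50.04,57.14,50.06
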