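dataset,algorithm,Se,Sp,G-Mean,F-Measure,AUC
Data1,IFSVM,86.50,99.00,92.75,90.81,92.75
Data1,RIFSVM,92.50,99.13,95.75,94.39,95.81
Data2,IFSVM,98.00,100.00,98.99,98.99,99.00
Data2,RIFSVM,100.00,100.00,100.00,100.00,100.00
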