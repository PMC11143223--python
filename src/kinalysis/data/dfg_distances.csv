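ligand,variant,d1,sd1,d2,sd2
trans-(-)-kusunokinin,WT,7.25,0.14,10.35,0.44
trans-(+)-kusunokinin,WT,7.37,0.16,11.01,0.27
Pexidartinib,WT,7.16,0.31,10.96,0.48
Imatinib,WT,7.07,0.14,10.55,0.07
Ligand-free,WT,7.21,0.34,11.30,0.25
trans-(-)-kusunokinin,W550A,7.67,0.13,10.94,0.42
trans-(+)-kusunokinin,W550A,7.62,0.22,10.01,0.32
Pexidartinib,W550A,7.52,0.17,10.27,0.50
Imatinib,W550A,7.39,0.02,10.15,0.38
Ligand-free,W550A,7.23,0.03,11.97,0.31
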