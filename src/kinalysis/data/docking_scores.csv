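ligand,group,score
trans-(-)-kusunokinin,test_compound,-11.47
trans-(+)-kusunokinin,test_compound,-9.87
Chiauranib,pan_tki,-12.96
Pazopanib,pan_tki,-11.95
Quizartinib,pan_tki,-11.54
Sorafenib,pan_tki,-11.46
Imatinib,pan_tki,-11.16
Linifanib,pan_tki,-10.99
Nilotinib,pan_tki,-10.58
Sunitinib,pan_tki,-10.11
Dasatinib,pan_tki,-9.93
Tandutinib,pan_tki,-9.67
OSI-930,pan_tki,-9.48
Sulfatinib,pan_tki,-9.15
Dovitinib,pan_tki,-8.95
Tinengotinib,pan_tki,-8.34
BPR1R024,csf1r_specific,-11.67
Pexidartinib,csf1r_specific,-11.07
Sotuletinib,csf1r_specific,-10.55
KI20227,csf1r_specific,-10.2
PLX5622,csf1r_specific,-9.96
IACS-9439,csf1r_specific,-9.90
JNJ28312141,csf1r_specific,-9.52
JTE-952,csf1r_specific,-9.51
Pimicotinib,csf1r_specific,-9.45
Edicotinib,csf1r_specific,-9.38
Vimseltinib,csf1r_specific,-9.25
GW2580,csf1r_specific,-8.87
ARRY-382,csf1r_specific,-8.75
Q27456873,csf1r_specific,-8.60
AZD7505,csf1r_specific,-7.97
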