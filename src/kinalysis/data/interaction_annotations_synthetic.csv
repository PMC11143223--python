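ligand,group,score,interactions
trans-(-)-kusunokinin,test_compound,-11.47,550:pi_stack
trans-(+)-kusunokinin,test_compound,-9.87,797:pi_t
Chiauranib,pan_tki,-12.96,550:pi_stack
Pazopanib,pan_tki,-11.95,550:pi_stack
Quizartinib,pan_tki,-11.54,550:pi_stack
Sorafenib,pan_tki,-11.46,550:pi_stack;797:pi_stack
Imatinib,pan_tki,-11.16,550:pi_stack;797:pi_t;665:pi_stack
Linifanib,pan_tki,-10.99,797:pi_stack
Nilotinib,pan_tki,-10.58,797:pi_stack
Sunitinib,pan_tki,-10.11,797:pi_stack
Dasatinib,pan_tki,-9.93,550:pi_stack
Tandutinib,pan_tki,-9.67,797:pi_stack
OSI-930,pan_tki,-9.48,797:pi_t
Sulfatinib,pan_tki,-9.15,none
Dovitinib,pan_tki,-8.95,none
Tinengotinib,pan_tki,-8.34,none
BPR1R024,csf1r_specific,-11.67,550:pi_stack
Pexidartinib,csf1r_specific,-11.07,550:pi_stack;797:pi_stack
Sotuletinib,csf1r_specific,-10.55,550:pi_stack
KI20227,csf1r_specific,-10.2,550:pi_stack
PLX5622,csf1r_specific,-9.96,797:pi_stack
IACS-9439,csf1r_specific,-9.90,797:pi_stack
JNJ28312141,csf1r_specific,-9.52,797:pi_stack
JTE-952,csf1r_specific,-9.51,797:pi_stack
Pimicotinib,csf1r_specific,-9.45,797:pi_stack
Edicotinib,csf1r_specific,-9.38,797:pi_t
Vimseltinib,csf1r_specific,-9.25,797:pi_t
GW2580,csf1r_specific,-8.87,none
ARRY-382,csf1r_specific,-8.75,none
Q27456873,csf1r_specific,-8.60,none
AZD7505,csf1r_specific,-7.97,none
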