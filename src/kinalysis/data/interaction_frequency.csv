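group,w550_pi_above,w550_pi_below,f797_pi_above,f797_pi_below
pan_tki,5,1,5,2
csf1r_specific,4,0,1,7
trans_minus_kusunokinin,1,0,0,0
trans_plus_kusunokinin,0,0,0,1
total,10,1,6,10
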