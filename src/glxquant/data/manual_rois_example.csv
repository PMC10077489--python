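loop_id,x0_um,y0_um,x1_um,y1_um
loop1,5.20,6.20,7.20,6.20
loop1,6.20,5.20,6.20,7.20
loop1,5.00,5.00,6.40,6.40
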