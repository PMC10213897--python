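# Food specimens: mean height/width/length (m) and mean chewing time (s).
# Carrot and sausage specimens are cylindrical; width equals height (diameter).
id,label,h_m,w_m,l_m,t_chew_s
d,dark chocolate,0.0091,0.0171,0.0262,0.51
b,chocolate bar,0.0201,0.0174,0.0303,1.12
a,apple,0.0235,0.0186,0.0265,1.31
c,carrot,0.0196,0.0196,0.0168,1.08
s,sausage,0.0272,0.0272,0.0174,1.51
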