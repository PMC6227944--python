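joint,side,x_mm,y_mm,z_mm
NV,midline,0.0,0.0,0.0
NS_L,left,36.0,-8.0,-6.0
NS_R,right,36.0,-8.0,6.0
HS_L,left,20.0,-29.0,-12.0
HS_R,right,20.0,-29.0,12.0
JQ_L,left,40.0,-18.0,-8.0
JQ_R,right,40.0,-18.0,8.0
CH_L,left,42.0,-31.0,-4.0
CH_R,right,42.0,-31.0,4.0
HYM,midline,46.0,-34.0,0.0
SYM,midline,53.0,-36.0,0.0
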