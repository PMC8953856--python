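scan,W1,Y2,K3,Y4,W5
ala,n.f.,5755,"10,467",1694,1060
d,881,892,4523,3243,3926
beta,4.3,60,332,40,86
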