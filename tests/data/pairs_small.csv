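study,ro,no,rr,nr,pm_belief
p01,0.45,32,0.21,65,0.6
p02,0.62,28,0.5,30,0.8
p03,0.21,120,0.05,240,0.35
p04,-0.35,45,-0.11,90,0.55
p05,0.18,60,0.24,60,0.7
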