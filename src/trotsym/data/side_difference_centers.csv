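variable,median_diff_mm,mean_diff_mm,normal
DHDmin,2.5,3.9,1
DHDmax,-2.5,-0.35,1
DHDup,-1.0,4.7,1
DHROM,1.0,,0
DWDmin,-0.5,-0.6,1
DWDmax,1.0,-0.8,0
DWDup,0.5,2.65,1
DWROM,2.0,,1
DPDmin,0.0,-0.1,1
DPDmax,1.5,1.55,1
DPDup,1.0,2.4,1
DPROM,-1.0,,0
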