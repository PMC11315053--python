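variable,p_direction,p_surface,emm_inside,lo_inside,hi_inside,emm_outside,lo_outside,hi_outside,emm_straight,lo_straight,hi_straight,emm_hard,lo_hard,hi_hard,emm_soft,lo_soft,hi_soft
DHDmin,0.946,0.068,-0.800,-4.401,2.801,-0.450,-4.051,3.151,-0.150,-2.486,2.186,-2.267,-6.038,1.504,1.333,-0.717,3.384
DHDmax,0.411,0.070,0.425,-2.670,3.520,-1.275,-4.370,1.820,0.725,-1.385,2.835,-1.517,-4.746,1.713,1.433,-0.464,3.331
DHDup,0.319,0.038,-0.800,-6.620,5.020,-3.050,-8.870,2.770,1.700,-2.114,5.514,-4.017,-10.107,2.074,2.583,-0.782,5.948
DHROM,0.721,0.795,0.775,-2.364,3.914,0.975,-2.164,4.114,-0.325,-2.308,1.658,0.250,-3.043,3.543,0.700,-1.016,2.416
DWDmin,0.313,0.017,-2.550,-4.313,-0.787,-1.550,-3.313,0.213,-1.150,-2.362,0.062,-2.900,-4.742,-1.058,-0.600,-1.715,0.515
DWDmax,0.016,0.107,1.250,0.012,2.538,-0.725,-1.988,0.538,-0.225,-1.005,0.555,0.683,-0.643,2.010,-0.467,-1.132,0.199
DWDup,0.639,0.439,-1.200,-3.344,0.944,-2.250,-4.394,-0.106,-1.450,-2.892,-0.008,-2.083,-4.327,0.160,-1.183,-2.499,0.132
DWROM,0.215,0.649,0.325,-2.127,2.777,-1.775,-4.227,0.677,-1.925,-3.341,-0.509,-1.450,-4.035,1.135,-0.800,-1.956,0.356
DPDmin,0.895,0.859,1.000,-0.941,2.941,0.600,-1.341,2.541,1.100,-0.020,2.220,0.800,-1.246,2.846,1.000,0.085,1.915
DPDmax,0.529,0.033,-1.325,-2.884,0.234,-0.625,-2.184,0.934,-1.475,-2.596,-0.354,-2.017,-3.641,-0.393,-0.267,-1.315,0.781
DPDup,0.999,0.230,-0.350,-3.056,2.356,-0.400,-3.106,2.306,-0.400,-1.962,1.162,-1.333,-4.185,1.519,0.567,-0.709,1.842
DPROM,0.091,0.869,-0.100,-2.293,2.093,1.800,-0.393,3.993,-0.800,-2.235,0.635,0.400,-1.899,2.699,0.200,-1.094,1.494
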