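variable,condition,median,p25,p75,min,max
HDmin,hard_straight,3.0,-4.0,14.5,-18,26
HDmax,hard_straight,1.0,-3.0,5.5,-11,9
HDup,hard_straight,7.0,-7.25,16.0,-22,38
HROM,hard_straight,77.0,70.75,79.75,58,93
WDmin,hard_straight,-4.0,-7.5,-1.0,-11,4
WDmax,hard_straight,-5.0,-9.0,4.0,-12,6
WDup,hard_straight,-9.5,-13.0,1.75,-22,11
WROM,hard_straight,96.5,91.0,105.0,84,108
PDmin,hard_straight,-3.5,-6.25,3.5,-7,13
PDmax,hard_straight,2.0,-4.0,7.5,-8,24
PDup,hard_straight,-2.5,-7.25,7.25,-12,39
PROM,hard_straight,98.0,91.5,102.0,76,112
HDmin,soft_straight,-0.5,-11.0,10.75,-21,27
HDmax,soft_straight,-3.0,-8.75,2.5,-22,6
HDup,soft_straight,-3.5,-18.0,6.0,-44,27
HROM,soft_straight,80.5,73.75,88.0,62,103
WDmin,soft_straight,-4.5,-7.0,-0.5,-11,8
WDmax,soft_straight,-4.5,-8.0,0.5,-14,5
WDup,soft_straight,-8.0,-14.5,-0.5,-24,9
WROM,soft_straight,101.5,94.0,112.25,87,117
PDmin,soft_straight,-5.0,-5.25,0.25,-6,12
PDmax,soft_straight,2.5,-4.0,7.25,-12,19
PDup,soft_straight,-2.0,-7.5,2.75,-13,28
PROM,soft_straight,102.0,98.75,111.0,76,112
HDmin,left_circle,-2.0,-11.75,11.25,-35,20
HDmax,left_circle,-7.0,-12.75,0.5,-16,15
HDup,left_circle,-4.0,-22.25,7.5,-50,28
HROM,left_circle,86.0,81.0,91.25,73,93
WDmin,left_circle,-18.0,-21.5,-11.5,-29,-8
WDmax,left_circle,0.5,-3.0,6.25,-7,13
WDup,left_circle,-15.5,-24.5,-7.75,-32,1
WROM,left_circle,103.0,97.5,112.75,87,122
PDmin,left_circle,-10.5,-21.25,-3.75,-23,0
PDmax,left_circle,6.5,-0.75,12.25,-10,16
PDup,left_circle,-7.0,-15.0,1.0,-18,8
PROM,left_circle,106.5,100.0,113.75,96,123
HDmin,right_circle,5.0,-6.0,16.5,-21,23
HDmax,right_circle,1.0,-6.25,4.25,-21,8
HDup,right_circle,3.5,-6.5,15.75,-36,32
HROM,right_circle,87.5,78.5,91.5,76,94
WDmin,right_circle,8.0,2.0,15.0,2,18
WDmax,right_circle,-8.5,-12.25,-3.5,-14,1
WDup,right_circle,3.0,-9.25,9.5,-13,17
WROM,right_circle,102.5,92.25,113.75,90,122
PDmin,right_circle,5.0,3.0,18.5,0,21
PDmax,right_circle,1.0,-3.0,6.5,-11,17
PDup,right_circle,7.0,3.5,22.75,-9,36
PROM,right_circle,109.0,102.75,115.25,89,118
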