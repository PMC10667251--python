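patient,dHY,dUPDRS3,dLDopa_mg,dADL,followup
J2C,3,24,400,-0.6,1
M89,3,53,1563,-0.6,1
C99,2.5,36,610,-0.5,1
R66,,,,,0
AY6,1,-1,800,-0.2,1
PX7,1,0,1900,-0.1,1
88H,2,7,640,-0.3,1
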