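case_id,iop_mmHg,bandwidth_mm,AL_pre_mm,AL_pos_mm,dAL_mm,dD33_D,dD67_D,dD100_D
1,11,2.5,24.860,25.382,0.522,-0.35,-0.58,-1.11
2,15,2.5,24.860,25.356,0.496,-0.24,-0.48,-1.05
3,18,2.5,24.860,25.359,0.499,-0.11,-0.32,-1.06
4,11,2.0,24.860,25.273,0.413,-0.29,-0.51,-0.88
5,15,2.0,24.860,25.219,0.359,-0.21,-0.37,-0.76
6,18,2.0,24.860,25.334,0.474,-0.11,-0.29,-1.01
7,11,1.0,24.860,25.022,0.162,-0.19,-0.27,-0.35
8,15,1.0,24.860,25.029,0.169,-0.19,-0.22,-0.36
9,18,1.0,24.860,25.149,0.289,-0.03,-0.06,-0.62
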