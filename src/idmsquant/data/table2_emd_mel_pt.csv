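role,quantity,value,u,n_repeats
sample_blend,m_sample,500.0,0.144,1
sample_blend,m_spike,594.0,0.229,1
sample_blend,ratio,1.02,0.025,1
calib_blend,m_standard,595.0,0.172,1
calib_blend,m_spike,598.0,0.173,1
calib_blend,ratio,0.97,0.030,1
standard,w_zc,10.0,0.14,1
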