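blend_id,m_x_mg,u_m_x_mg,m_y_mg,u_m_y_mg,m_z_mg,u_m_z_mg,r_obs,u_r_obs,n_repeats
1,48.510,0.049,49.002,0.049,0.000,0.0,1.217,0.013,3
2,49.523,0.050,99.193,0.099,49.053,0.049,1.231,0.038,3
3,48.851,0.049,147.450,0.147,98.266,0.098,1.224,0.020,3
4,47.388,0.047,198.577,0.199,148.252,0.148,1.213,0.005,3
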