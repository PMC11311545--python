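blend_id,m_x_mg,u_m_x_mg,m_y_mg,u_m_y_mg,m_z_mg,u_m_z_mg,r_obs,u_r_obs,n_repeats
1,500.770,0.501,99.340,0.099,0.000,0.0,10.428,0.209,2
2,502.790,0.503,101.460,0.101,49.430,0.049,10.877,0.218,2
3,500.760,0.501,100.460,0.100,99.320,0.099,11.787,0.236,2
4,507.570,0.508,100.670,0.101,149.410,0.149,12.822,0.256,2
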