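blend_id,m_x_mg,u_m_x_mg,m_y_mg,u_m_y_mg,m_z_mg,u_m_z_mg,r_obs,u_r_obs,n_repeats
1,48.695,0.049,48.943,0.049,0.000,0.0,1.051,0.007,3
2,48.218,0.048,98.725,0.099,48.900,0.049,1.048,0.003,3
3,49.055,0.049,147.418,0.147,98.247,0.098,1.067,0.014,3
4,48.991,0.049,197.813,0.198,147.505,0.148,1.057,0.008,3
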