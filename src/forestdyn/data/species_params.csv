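code,name,components,vol_a,vol_b,vol_c,wood_density,bef,root_shoot,cutting_age,base_si,dbh_asym,dbh_rate,dbh_shape,dens_gamma,n_ref,clim_opt,clim_width,h_rate,h_shape,mort_a,mort_b,nmax_k1,nmax_k2,nmax_hcoef,planting_density,felling_cost_krw_m3,transport_cost_krw_m3,reforest_price_krw_ha,log_price_krw_m3
red_pine,Pinus densiflora,,0.000201,1.7593,0.6583,0.472,1.413,1.254,60,14,38.838,0.0165,1.25,0.25,1000,0.0,2.6,0.04,1.15,0.095,2.0,85000,-1.605,0.02,3000,18622.0,21939,6176827.0,75000
korean_pine,Pinus koraiensis,,1.5e-05,2.4239,0.8651,0.408,1.812,1.283,60,14,43.894,0.0143,1.3,0.25,1000,0.0,2.2,0.04,1.15,0.095,2.0,90000,-1.605,0.02,3000,16356.0,20508,6474693.0,90000
larch,Larix kaempferi,,8.8e-05,1.7828,0.9397,0.453,1.335,1.291,50,14,41.964,0.01925,1.2,0.25,1000,0.0,2.2,0.042,1.12,0.095,2.0,80000,-1.605,0.02,3000,19246.0,20508,6072753.0,70000
cork_oak,Quercus variabilis,,4.7e-05,1.8603,1.0589,0.721,1.338,1.324,60,14,38.096,0.0154,1.25,0.25,1000,0.8,3.2,0.045,1.05,0.095,2.0,70000,-1.605,0.02,3000,20747.0,21939,6288078.0,90000
mongolian_oak,Quercus mongolica,,0.000344,1.3639,0.8792,0.663,1.603,1.388,60,14,38.041,0.0143,1.3,0.25,1000,0.8,3.2,0.045,1.05,0.095,2.0,70000,-1.605,0.02,3000,20747.0,21939,7269601.0,85000
mixed_a,Mixed forest A (red pine / cork oak),red_pine+cork_oak,,,,0.5965,1.375,1.289,60,14,38.469,0.01595,1.25,0.25,1000,0.4,2.9,0.0425,1.1,0.095,2.0,77500,-1.605,0.02,3000,19684.5,21939,6232452.5,82500
mixed_b,Mixed forest B (red pine / Mongolian oak),red_pine+mongolian_oak,,,,0.5675,1.508,1.321,60,14,38.44,0.0154,1.275,0.25,1000,0.4,2.9,0.0425,1.1,0.095,2.0,77500,-1.605,0.02,3000,19684.5,21939,6723214.0,80000
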