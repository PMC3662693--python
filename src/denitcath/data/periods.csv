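period_id,regime,flow_l_per_d,cod_in,cod_out,no3_in,no3_out,no2_in,no2_out,n2o_out,n2_out,current_density_a_per_m3,ncc_volume_m3
period1,autotrophic_nitrate,2.0,n.d.,n.d.,26.6,22.6,0.3,0.2,0.6,3.5,15.0,0.000145
period2,heterotrophic_nitrate,1.4,64,31,29.6,20.7,1.0,2.1,4.0,3.8,11.0,0.000145
period3,autotrophic_nitrite,1.2,n.d.,n.d.,2.9,0.0,20.3,4.6,13.0,5.6,14.1,0.000145
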