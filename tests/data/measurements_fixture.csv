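bundle_id,cell_type,stereocilium_id,row,kind,side,stage_tilt_deg,parallel_angle_deg,value_um,row_spacing_um
b1,OHC,s1,1,full_length,lateral,-30.0,10.0,1.543081,0.4
b1,OHC,s2,2,step_1_to_2,medial,50.0,10.0,0.385673,0.4
b1,OHC,s3,unranked,full_length,lateral,-30.0,10.0,0.225100,0.4
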