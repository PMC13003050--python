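hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
LTH,LT,cold,clinic,0.9,220,1
LTH,LT,cold,patient room,0.9,225,2
LTH,LT,cold,emergency room,0.9,230,3
LTH,LT,cold,intensive care unit,0.9,235,4
LTH,LT,cold,operation room,0.9,240,5
LTH,LT,cold,clinic,0.9,245,1
LTH,LT,cold,administrative office,0.5,250,2
LTH,LT,cold,pharmacy,0.5,255,3
LTH,LT,cold,laboratory,0.5,260,4
LTH,LT,cold,administrative office,0.5,265,5
LTH,LT,cold,pharmacy,0.5,270,1
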