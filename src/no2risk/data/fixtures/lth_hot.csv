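hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
LTH,LT,hot,clinic,0.9,270,1
LTH,LT,hot,patient room,0.9,276,2
LTH,LT,hot,emergency room,0.9,282,3
LTH,LT,hot,intensive care unit,0.9,288,4
LTH,LT,hot,operation room,0.9,294,5
LTH,LT,hot,clinic,0.9,300,1
LTH,LT,hot,administrative office,0.5,306,2
LTH,LT,hot,pharmacy,0.5,312,3
LTH,LT,hot,laboratory,0.5,318,4
LTH,LT,hot,administrative office,0.5,324,5
LTH,LT,hot,pharmacy,0.5,330,1
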