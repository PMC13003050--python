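hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
MTH,MT,cold,clinic,0.9,360,1
MTH,MT,cold,patient room,0.9,361.25,2
MTH,MT,cold,emergency room,0.9,362.5,3
MTH,MT,cold,intensive care unit,0.9,363.75,4
MTH,MT,cold,operation room,0.9,365,5
MTH,MT,cold,clinic,0.9,366.25,1
MTH,MT,cold,patient room,0.9,367.5,2
MTH,MT,cold,administrative office,0.5,368.75,3
MTH,MT,cold,pharmacy,0.5,370,4
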