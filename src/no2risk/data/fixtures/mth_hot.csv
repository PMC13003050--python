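hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
MTH,MT,hot,clinic,0.9,460,1
MTH,MT,hot,patient room,0.9,462.5,2
MTH,MT,hot,emergency room,0.9,465,3
MTH,MT,hot,intensive care unit,0.9,467.5,4
MTH,MT,hot,operation room,0.9,470,5
MTH,MT,hot,clinic,0.9,472.5,1
MTH,MT,hot,patient room,0.9,475,2
MTH,MT,hot,administrative office,0.5,477.5,3
MTH,MT,hot,pharmacy,0.5,480,4
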