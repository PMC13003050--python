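hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
OSH,OS,cold,clinic,0.9,170,1
OSH,OS,cold,patient room,0.9,186.67,2
OSH,OS,cold,emergency room,0.9,203.33,3
OSH,OS,cold,intensive care unit,0.9,220,4
OSH,OS,cold,administrative office,0.5,236.67,5
OSH,OS,cold,pharmacy,0.5,253.33,1
OSH,OS,cold,laboratory,0.5,270,2
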