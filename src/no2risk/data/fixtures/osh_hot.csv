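hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
OSH,OS,hot,clinic,0.9,270,1
OSH,OS,hot,patient room,0.9,293.33,2
OSH,OS,hot,emergency room,0.9,316.67,3
OSH,OS,hot,intensive care unit,0.9,340,4
OSH,OS,hot,administrative office,0.5,363.33,5
OSH,OS,hot,pharmacy,0.5,386.67,1
OSH,OS,hot,laboratory,0.5,410,2
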