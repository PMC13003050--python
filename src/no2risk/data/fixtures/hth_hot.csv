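hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
HTH,HT,hot,clinic,0.9,770,1
HTH,HT,hot,patient room,0.9,786,2
HTH,HT,hot,emergency room,0.9,802,3
HTH,HT,hot,intensive care unit,0.9,818,4
HTH,HT,hot,operation room,0.9,834,5
HTH,HT,hot,clinic,0.9,850,1
HTH,HT,hot,patient room,0.9,866,2
HTH,HT,hot,emergency room,0.9,882,3
HTH,HT,hot,administrative office,0.5,898,4
HTH,HT,hot,pharmacy,0.5,914,5
HTH,HT,hot,laboratory,0.5,930,1
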