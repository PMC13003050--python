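hospital_id,traffic,season,location_label,occupancy_fraction,concentration,n_staff
HTH,HT,cold,clinic,0.9,500,1
HTH,HT,cold,patient room,0.9,510,2
HTH,HT,cold,emergency room,0.9,520,3
HTH,HT,cold,intensive care unit,0.9,530,4
HTH,HT,cold,operation room,0.9,540,5
HTH,HT,cold,clinic,0.9,550,1
HTH,HT,cold,patient room,0.9,560,2
HTH,HT,cold,administrative office,0.5,570,3
HTH,HT,cold,pharmacy,0.5,580,4
HTH,HT,cold,laboratory,0.5,590,5
HTH,HT,cold,administrative office,0.5,600,1
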