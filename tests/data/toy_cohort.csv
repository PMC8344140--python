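patient_id,age,sex,comorbidity_index,ais_head,ais_neck,ais_thorax,ais_abdomen,ais_spine,ais_upper_ext,ais_lower_ext,ais_face,ais_skin,ais_unspecified,gcs,sbp,pulse,rr,saturation,transport_mode,center_level,transferred_in,no_vitals_at_arrival,travel_time_min,mortality
1,45,male,0,3,0,2,0,0,0,1,0,0,0,14,120,95,18,97,ambulance,1,0,0,40,0
2,30,female,0,2,0,0,0,0,0,0,0,0,0,15,130,80,16,99,self,1,0,0,20,0
3,50,male,1,0,0,3,2,0,0,0,0,0,0,15,125,88,18,96,other,2,0,0,35,1
4,16,male,0,4,0,0,0,0,0,0,0,0,0,13,110,100,20,98,ambulance,1,0,0,30,0
5,40,female,0,0,0,0,0,0,0,3,0,0,0,15,135,85,16,99,ambulance,2,0,0,25,0
6,60,male,2,1,0,0,0,0,0,0,0,0,0,15,140,90,18,97,ambulance,1,0,0,45,0
7,55,male,0,5,0,4,0,0,0,0,0,0,0,3,0,0,0,60,helicopter,1,0,1,50,1
8,35,female,0,3,0,0,2,0,0,0,0,0,0,15,118,92,18,98,ambulance,4,0,0,55,0
9,70,male,3,0,0,3,0,2,0,0,0,0,0,14,150,85,16,95,ambulance,,0,0,60,0
10,65,female,1,2,2,3,0,0,0,0,0,0,0,15,128,98,20,96,ambulance,2,0,0,30,
11,28,male,0,4,0,0,3,0,0,2,0,0,0,9,100,110,24,92,helicopter,2,0,0,65,1
12,80,female,4,3,0,2,2,0,0,0,0,0,0,15,160,70,14,94,ambulance,1,1,0,70,1
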