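id,taxon,element,section_modulus_length_corrected,wingspan_m,mass_kg,rff,avian_expectation,ratio_printed,ratio_consistent
USNM 11925,Bennettazhia oregonensis,humerus,3.43,2.80,6.10,7.16,2.69,2.66,1
MOR 691,Montanazhdarcho minor,humerus,2.75,3.00,7.26,4.84,2.55,1.90,1
TMM 41961,Quetzalcoatlus sp.,humerus,8.37,4.70,22.34,4.78,1.78,2.69,1
TMM 41961,Quetzalcoatlus sp.,cervical,3.51,4.70,22.34,2.00,,,
TMM 41961,Quetzalcoatlus sp.,femur,1.66,4.70,22.34,0.95,3.15,0.30,1
TMM 41450,Quetzalcoatlus northropi,humerus,36.18,10.40,180.00,2.56,0.91,2.82,0
TMM 41450,Quetzalcoatlus northropi,humerus,36.18,10.40,200.00,2.31,0.88,2.62,0
TMM 41450,Quetzalcoatlus northropi,humerus,36.18,10.40,250.00,1.85,0.82,2.25,0
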