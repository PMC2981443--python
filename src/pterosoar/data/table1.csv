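taxon,common_name,span_m,mass_kg,area_m2,weight_N,aspect_ratio,wing_loading,reference,derived_consistent
Pteranodon,,6.95,14.95,2.53,146.56,19.10,57.93,Brower & Veinus,1
Pteranodon,,6.95,16.6,4.62,162.85,10.455,35.248,Hazlehurst & Rayner,1
Pteranodon,,6.95,16.60,2.65,162.85,18.23,61.45,Chatterjee & Templin,1
Pteranodon,,5.43,36.68,1.60,359.84,18.42,224.79,Witton,1
Quetzalcoatlus,,10.39,70.00,9.55,686.70,11.30,71.91,Chatterjee & Templin,1
Quetzalcoatlus,,9.64,259.06,11.36,2541.40,8.18,223.66,Witton,1
Diomedea exulans,Wandering albatross,3.46,8.16,0.66,80.05,18.00,120.71,Savile,1
Diomedea exulans,Wandering albatross,3.03,8.73,0.61,85.64,15.03,140.17,Pennycuick,1
Diomedea irrorata,Waved albatross,2.31,2.04,0.36,20.01,15.00,56.11,Savile,0
Thalassarche melanophrys,Black-browed albatross,2.16,3.79,0.36,37.18,13.11,104.44,Pennycuick,0
Thalassarche chrysostoma,Grey-headed albatross,2.18,3.79,0.35,37.18,13.50,105.62,Pennycuick,1
Phoebetria sp.,Sooty albatross,2.18,2.84,0.34,27.86,14.06,82.43,Pennycuick,1
Macronectes sp.,Giant petrel,1.99,5.19,0.33,50.91,11.96,153.82,Pennycuick,1
Procellaria aequinoctialis,White-chinned petrel,1.40,1.37,0.17,13.44,11.60,79.52,Pennycuick,1
Fulmarus sp.,Fulmar,1.13,0.82,0.12,8.00,10.30,64.48,Pennycuick,0
Puffinus pacificus,Wedge-tailed shearwater,1.01,0.38,0.10,3.73,10.20,37.28,Hertel,1
Puffinus nativitatis,Christmas shearwater,0.82,0.34,0.07,3.34,9.61,47.65,Hertel,1
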