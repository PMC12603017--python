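category,density_g_cm3,packing_mu,kcal_100g,protein_100g,carb_100g,fat_100g,fiber_100g
broccoli,1.0,0.7,34,2.8,6.6,0.4,2.6
chicken,1.0,1.0,165,31.0,0.0,3.6,0.0
rice,1.0,1.0,130,2.7,28.2,0.3,0.4
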