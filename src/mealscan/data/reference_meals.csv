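food,sequence,reference_g,volume_cm3,effective_factor
broccoli,1,11.5,18.3859,0.7
broccoli,2,14.5,17.3806,0.7
broccoli,3,14.0,26.13619,0.7
broccoli,4,9.5,12.7545,0.7
broccoli,5,12.3,15.8179,0.7
broccoli,0,,93.9942,0.7
chicken,1,30.8,30.4084,1.0
chicken,2,46.4,43.6534,1.0
chicken,3,47.3,34.8367,1.0
chicken,4,39.2,33.5642,1.0
chicken,0,,155.6516,1.0
rice,1,36.5,28.6671,1.0
rice,2,31.8,31.3682,1.0
rice,3,39.7,39.8051,1.0
rice,4,23.8,16.5793,1.0
rice,5,36.3,40.5053,1.0
rice,0,,183.6207,1.0
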