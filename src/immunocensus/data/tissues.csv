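tissue_id,group,specific_gravity,mass_male_g,mass_female_g,mass_child_g
bone_marrow,bone marrow,1.03,1170,900,630
spleen,lymphatic,1.03,150,130,80
lymph_nodes,lymphatic,1.03,185,,
thymus,lymphatic,1.03,25,20,30
tonsils,lymphatic,1.03,3,3,3
blood,blood,1.03,5600,4100,2400
skin,barrier epithelial,1.03,3300,2300,1400
lungs,barrier epithelial,1.03,1200,950,500
small_intestine,barrier epithelial,1.03,640,600,370
large_intestine,barrier epithelial,1.03,370,360,210
stomach,barrier epithelial,1.03,150,140,85
liver,other epithelial,1.03,1800,1400,830
kidneys,other epithelial,1.03,310,275,180
pancreas,other epithelial,1.03,140,120,60
heart,striated muscle,1.03,330,250,150
skeletal_muscle,striated muscle,1.03,29000,17500,11000
adipose,adipose,0.91,14500,22500,7000
brain,CNS,1.03,1450,1300,1310
connective,other connective,1.03,3000,2500,1500
ecf_matrix,extracellular fluids and matrix,1.03,9000,4000,3000
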