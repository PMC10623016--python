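cell_type,total_number,number_ci_low,number_ci_high,total_mass_g,mass_ci_low,mass_ci_high
T cell,5e11,3e11,7e11,100,60,150
B cell,3e11,2e11,4e11,60,40,90
plasma cell,2e10,5e9,6e10,30,4,170
NK cell,2e10,9e9,4e10,4,2,8
mast cell,9e10,6e10,1.4e11,100,40,200
neutrophil,7e11,5e11,8e11,200,160,300
eosinophil,4e10,2e10,8e10,10,5,20
basophil,2e9,4e8,7e9,0.7,0.2,3
macrophage,2e11,1.3e11,3e11,600,300,1400
monocyte,3e10,2e10,4e10,13,9,20
dendritic cell,5e10,3e10,8e10,100,40,300
total,1.8e12,1.5e12,2.3e12,1200,800,1900
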