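compound_id,phase,I_eV,A_eV,display_name,method_tag,homo_eV,lumo_eV,ic50_ppm
lupinifolin,gas,7.15,0.07,,,-5.759,,128.64
lupinifolin,methanol,5.77,1.71,,,-5.759,,128.64
citflavanone,gas,7.24,-0.01,,,-5.7835,,548.72
citflavanone,methanol,5.76,1.74,,,-5.7835,,548.72
lonchocarpol_a,gas,7.24,-0.1,,,-5.895,,441.49
lonchocarpol_a,methanol,5.98,1.65,,,-5.895,,441.49
quercetin,gas,8.03,2.99,,,,,8.14
ascorbic_acid,gas,9.74,3.06,,,,,4.53
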