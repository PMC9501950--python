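compound_id,charge_state,phase,energy_hartree,display_name,method_tag,homo_eV,lumo_eV,ic50_ppm
lupinifolin,anion,gas,-500.0025724525756,,synthetic,-5.759,,128.64
lupinifolin,cation,gas,-499.73724234406876,,synthetic,-5.759,,128.64
lupinifolin,neutral,gas,-500.0,,synthetic,-5.759,,128.64
lupinifolin,anion,methanol,-500.0628413414884,,synthetic,-5.759,,128.64
lupinifolin,cation,methanol,-499.7879564091296,,synthetic,-5.759,,128.64
lupinifolin,neutral,methanol,-500.0,,synthetic,-5.759,,128.64
citflavanone,anion,gas,-499.9996325067749,,synthetic,-5.7835,,548.72
citflavanone,cation,gas,-499.73393490504304,,synthetic,-5.7835,,548.72
citflavanone,neutral,gas,-500.0,,synthetic,-5.7835,,548.72
citflavanone,anion,methanol,-500.06394382116366,,synthetic,-5.7835,,548.72
citflavanone,cation,methanol,-499.7883239023547,,synthetic,-5.7835,,548.72
citflavanone,neutral,methanol,-500.0,,synthetic,-5.7835,,548.72
lonchocarpol_a,anion,gas,-499.99632506774924,,synthetic,-5.895,,441.49
lonchocarpol_a,cation,gas,-499.73393490504304,,synthetic,-5.895,,441.49
lonchocarpol_a,neutral,gas,-500.0,,synthetic,-5.895,,441.49
lonchocarpol_a,anion,methanol,-500.060636382138,,synthetic,-5.895,,441.49
lonchocarpol_a,cation,methanol,-499.780239051403,,synthetic,-5.895,,441.49
lonchocarpol_a,neutral,methanol,-500.0,,synthetic,-5.895,,441.49
quercetin,anion,gas,-500.1098804742985,,synthetic,,,8.14
quercetin,cation,gas,-499.70490294026183,,synthetic,,,8.14
quercetin,neutral,gas,-500.0,,synthetic,,,8.14
ascorbic_acid,anion,gas,-500.1124529268741,,synthetic,,,4.53
ascorbic_acid,cation,gas,-499.6420615987734,,synthetic,,,4.53
ascorbic_acid,neutral,gas,-500.0,,synthetic,,,4.53
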