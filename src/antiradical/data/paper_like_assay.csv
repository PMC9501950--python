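compound_id,concentration_ppm,inhibition_pct
lupinifolin,2.0,1.6128724828321648
lupinifolin,6.0,4.381212619675631
lupinifolin,18.0,12.785150581123835
lupinifolin,54.0,28.663013180540712
lupinifolin,162.0,56.18071097187423
lupinifolin,486.0,78.91900829303472
lupinifolin,1458.0,87.34287664360156
lupinifolin,4374.0,96.42966390965216
citflavanone,2.0,0.3675313865030446
citflavanone,6.0,1.1065392047112297
citflavanone,18.0,3.089813938445077
citflavanone,54.0,8.999173706113465
citflavanone,162.0,22.440087397682472
citflavanone,486.0,47.72891414254009
citflavanone,1458.0,72.36724604622943
citflavanone,4374.0,86.04787314162473
lonchocarpol_a,2.0,0.46024809464882543
lonchocarpol_a,6.0,1.3848422098550892
lonchocarpol_a,18.0,4.007229543766956
lonchocarpol_a,54.0,10.686182591634033
lonchocarpol_a,162.0,26.096095658211233
lonchocarpol_a,486.0,52.469907877313084
lonchocarpol_a,1458.0,78.07974734097799
lonchocarpol_a,4374.0,91.75688582393526
quercetin,2.0,18.847631607201034
quercetin,6.0,42.454879478910534
quercetin,18.0,68.11771672789956
quercetin,54.0,84.93799775101326
quercetin,162.0,90.56562364414553
quercetin,486.0,99.85825969132836
quercetin,1458.0,97.9338177451419
quercetin,4374.0,100.3472464853299
ascorbic_acid,2.0,30.142038300056416
ascorbic_acid,6.0,57.25421228893251
ascorbic_acid,18.0,76.86339331621987
ascorbic_acid,54.0,94.83586784028257
ascorbic_acid,162.0,98.5216327151909
ascorbic_acid,486.0,98.49780817557902
ascorbic_acid,1458.0,99.0682965539151
ascorbic_acid,4374.0,100.503582662978
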