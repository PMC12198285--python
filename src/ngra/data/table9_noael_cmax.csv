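chemical_id,tissue,endpoint,c_interst,c_intracel
bifenthrin,Plasma,peripheral_general,0.1,0.1
bifenthrin,Brain,brain_neuro_repeated,0.06,243.15
bifenthrin,Kidney,kidney_long_term,0.07,152.37
bifenthrin,Liver,liver_long_term,0.07,167.96
bifenthrin,Lung,lung_long_term,0.07,198.59
bifenthrin,Skin,skin_short_term,0.04,306.53
cyfluthrin,Plasma,peripheral_general,0.1,0.1
cyfluthrin,Brain,brain_neuro_repeated,0.04,296.29
cyfluthrin,Kidney,kidney_long_term,0.12,458.76
cyfluthrin,Liver,liver_long_term,0.13,502.24
cyfluthrin,Lung,lung_long_term,0.12,598.14
cyfluthrin,Skin,skin_short_term,0.11,129.59
cypermethrin,Plasma,peripheral_general,0.32,0.32
cypermethrin,Brain,brain_neuro_repeated,0.25,2209.14
cypermethrin,Kidney,kidney_long_term,0.14,386.17
cypermethrin,Liver,liver_long_term,0.14,427.29
cypermethrin,Lung,lung_long_term,0.14,503.03
cypermethrin,Skin,skin_short_term,0.22,1914.86
deltamethrin,Plasma,peripheral_general,2.28e-3,2.28e-3
deltamethrin,Brain,brain_neuro_repeated,1.12e-3,4.09
deltamethrin,Kidney,kidney_long_term,9.71e-4,2.32
deltamethrin,Liver,liver_long_term,9.88e-4,2.52
deltamethrin,Lung,lung_long_term,9.71e-4,3.01
deltamethrin,Skin,skin_short_term,,
l-cyhalothrin,Plasma,peripheral_general,9.28e-3,9.28e-3
l-cyhalothrin,Brain,brain_neuro_repeated,4.51e-3,10.96
l-cyhalothrin,Kidney,kidney_long_term,5.45e-3,7.49
l-cyhalothrin,Liver,liver_long_term,5.56e-3,8.17
l-cyhalothrin,Lung,lung_long_term,5.46e-3,9.77
l-cyhalothrin,Skin,skin_short_term,4.52e-3,19.26
permethrin,Plasma,peripheral_general,0.07,0.07
permethrin,Brain,brain_neuro_repeated,,
permethrin,Kidney,kidney_long_term,0.03,214.29
permethrin,Liver,liver_long_term,0.03,236.79
permethrin,Lung,lung_long_term,0.03,279.49
permethrin,Skin,skin_short_term,,
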