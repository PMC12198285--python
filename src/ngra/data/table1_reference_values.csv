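chemical_id,peripheral_general,brain_neuro_repeated,kidney_long_term,liver_long_term,lung_long_term,skin_short_term,adi
bifenthrin,1.5,2.9,4.7,4.7,4.7,1.5,0.015
cyfluthrin,2,2,12,12,12,6.5,0.02
cypermethrin,5,20,5,5,5,12.5,0.05
deltamethrin,1,4,1,1,1,,0.36
l-cyhalothrin,0.25,0.5,1.7,1.7,1.7,0.5,0.0025
permethrin,5,,5,5,5,,0.05
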