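chemical_id,molecular_weight,water_solubility,fraction_unbound,log_p,pka,intestinal_permeability,km,kcat,oral_dose
bifenthrin,422.9,4.4e-05,0.10,5.71,-7.1,4.37e-4,7.83,,1.35e-04
cyfluthrin,434.3,6.57e-04,0.10,5.93,10.49,1.04e-4,37.20,15,1.12e-04
cypermethrin,416.3,8.64e-04,0.10,5.81,10.65,1.09e-4,41.34,91,1.14e-03
deltamethrin,505.2,1.3e-06,0.10,5.74,10.65,1.64e-4,1.53,160,2e-04
l-cyhalothrin,449.85,5e-03,0.10,5.5,,1.28e-4,0.62,,2.42e-04
permethrin,391.3,6.91e-05,0.10,6.24,-3.7,4.4e-4,7.7,9.1,8.58e-04
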