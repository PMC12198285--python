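category,bifenthrin,cyfluthrin,cypermethrin,deltamethrin,l-cyhalothrin,permethrin
Breast,52.24,75.14,51.02,69.69,40.00,76.02
Intestine,26.84,19.46,59.82,46.82,,
Kidney,30.09,33.44,33.56,27.49,35.90,33.62
Liver,29.75,22.82,26.03,15.57,13.19,26.84
Lung,,,,0.96,0.59,
Immune system,14.70,41.30,66.95,60.38,44.09,
Brain,3.12,4.60,8.21,11.03,7.60,21.14
Ovary,52.61,32.06,9.96,52.55,53.26,3.36
Pancreas,,,20.44,,,
Prostate function,39.40,38.91,51.28,43.66,29.41,
Skin,5.78,12.42,,2.59,1.55,5.78
Vascular system,7.14,12.23,8.43,8.48,8.25,7.14
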