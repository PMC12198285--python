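category,bifenthrin,cyfluthrin,cypermethrin,deltamethrin,l-cyhalothrin,permethrin
Breast,0.77,0.53,0.78,0.57,1.00,0.53
Intestine,0.73,1.00,0.33,0.42,,
Kidney,0.91,0.82,0.82,1.00,0.77,0.82
Liver,0.44,0.58,0.51,0.85,1.00,0.49
Lung,,,,0.61,1.00,
Immune system,1.00,0.36,0.22,0.24,0.33,
Brain,1.00,0.68,0.38,0.28,0.41,0.15
Ovary,0.06,0.10,0.34,0.06,0.06,1.00
Pancreas,,,1.00,,,
Prostate function,0.75,0.76,0.57,0.67,1.00,
Skin,0.27,0.12,,0.60,1.00,0.27
Vascular system,1.00,0.58,0.85,0.84,0.87,1.00
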